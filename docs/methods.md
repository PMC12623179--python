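# Methods

## The comparison problem

Bulk RNA-seq of dermal fibroblasts from two rodent species cannot be compared
on raw counts: the reference CDS sets differ in size and annotation depth,
library depths differ, and gene lengths differ between orthologs. The package
therefore separates two questions:

1. *Within a species*, does the TLR2 agonist change a gene's expression?
   Answered by paired fold changes and paired *t*-tests across cell lines.
2. *Between species*, is a gene expressed at a different level? Answered on a
   scale that removes library and length effects and anchors both species to a
   common physiological reference — the ratio to *Gapdh* in the same sample.

## Normalization chain

For counts `c_gs` (gene g, sample s) with library total `N_s` and CDS length
`L_g` (bp):

- **total-count**: `v = c_gs / N_s × 10⁶` (CPM; the 10⁶ is cosmetic and
  cancels in all downstream ratios),
- **per-kb**: `v ← v / (L_g / 1000)`,
- **gapdh-ratio**: `v ← v / v[Gapdh, s]`, making the reference row exactly 1
  and leaving all between-gene ratios within a sample unchanged.

TPM is the per-kb rate rescaled so each sample sums to 10⁶ (used only for the
expression filter, TPM ≥ 10 in at least one sample or in the across-sample
mean). TMM factors follow the edgeR algorithm (reference sample = closest
75th count-fraction percentile to the mean; 30%/5% two-sided trims on M and
A; precision-weighted mean of M; factors rescaled to geometric mean 1) and
are verified against Bioconductor edgeR in the test suite. Every product
carries a provenance list so downstream stages can assert the chain they
received.

The full chain is invariant to library-depth rescaling, and applying the
*Gapdh* ratio twice is idempotent. Zeros are never patched inside the chain
(so TPM sums stay exact); a pseudocount enters only at ratio time, see below.

## Paired differential expression

Each cell line contributes one treated/control ratio per gene (the pairing is
a split of the same second-passage culture into exposure arms). The fold
change is the geometric mean of per-line ratios, so that
`ln FC = mean(ln ratio)` exactly — means of LN ratios are the symmetric,
recommended effect scale for ratios, and the paired *t*-test is applied to
exactly those per-line LN ratios (two-tailed, against 0). DEGs require both
FC ≥ 2 (or ≤ 0.5) and *p* < 0.001; FC boundaries are inclusive, the *p*
boundary strict. Benjamini–Hochberg q-values are attached
(`q_(i) = min_{j≥i} m·p_(j)/j`), and because the FDR bound implied by a fixed
*p* threshold is dataset-dependent, results report the *realized* maximum q
among sub-threshold tests rather than hard-coding a printed bound.

Numerical conventions:

- Zero-variance LN ratios yield `p = NaN` (an explicit undefined flag, never
  0); flagged tests are excluded from the BH ranking and never called.
- When building from raw counts, a pseudocount (default 0.5 on the count
  scale, where it has its usual meaning) is added to all counts only if any
  zero is present, and the application is logged. Adding it on a normalized
  scale instead would crush fold changes of well-measured genes — values on
  the *Gapdh*-ratio scale are of order 10⁻²–10⁰ — so the count scale is the
  only correct place.
- Species specificity: a response is species-specific when the two species'
  fold changes differ ≥ 10-fold (boundary inclusive), otherwise shared.
- Cross-species expression ratios are ratios of species means of
  *Gapdh*-normalized values with an unpaired two-tailed *t* on LN values.
- Fisher exact (two-tailed, sum of hypergeometric probabilities ≤ observed),
  Kruskal–Wallis (tie-corrected, retained for two groups where it is a
  tie-corrected rank test) and the paired/unpaired *t*-tests are delegated to
  scipy/statsmodels; the package's own tests check them against enumeration
  and closed-form oracles.

## ERV / transposable-element analyses

Repeat intervals are stored zero-based end-exclusive, a convention forced by
the published locus/length pairs (e.g. 6812577–6822120 → 9,543 bp); one-based
inclusive input is converted on read. Analyses: the ≥ 500 bp filter (with
excluded fraction reported), Z-scores of lengths against the complete
reference set and of mean TPM against the expressed (TPM-filtered) subset,
and top-k subsets by mean TPM with deterministic tie-breaking (higher TPM,
then longer, then lexicographic id).

Conventions that change magnitudes, hence fixed and documented:

- sample (n−1) standard deviations everywhere, including Z-scores;
- skewness is the adjusted Fisher–Pearson coefficient
  `g1·√(n(n−1))/(n−2)` — the common spreadsheet/stat-package convention; the
  source data's convention is not recoverable, so this choice is documented
  rather than asserted to match;
- "mean TPM across all conditions" is the unweighted mean over all samples;
- percentages use half-up rounding (verified against every published
  count/percent pair used in the tests: 21/87 → 24, 19/21 → 90,
  832/10843 → 7.7, 1136/10843 → 10.5, 10843/103397 → 10.5).

The length-vs-expression regression is ordinary least squares with t-based
95% limits for the conditional mean (LCL/UCL) and for a new observation
(LPL/UPL), computed by statsmodels `get_prediction`; the pointwise ordering
LPL ≤ LCL ≤ mean ≤ UCL ≤ UPL holds by construction and is property-tested.
The regression runs on untransformed TPM vs bp by default with a log-TPM
option, since the appropriate scale is a modelling choice.

Low- vs high-passage contrasts report signed fold changes (negative = higher
in the second group) over the expressed universe (mean TPM ≥ threshold),
with an unpaired *t* on ln(TPM + 0.5) plus BH as the in-package test; an
externally computed FC/FDR table can be supplied instead, since GLM-based
count tests are deliberately out of scope here.

## Kozak-context ORF scanning

An ORF qualifies iff it starts at ATG (A = +1), extends ≥ 30 codons to the
first in-frame stop wholly inside the sequence, and has a purine (A/G,
exactly; ambiguity codes disqualify) at −3 and G at +4. Position +4 is the
first base of codon 2, always inside the ORF; position −3 requires ≥ 3
upstream bases on the scanned strand, and an ATG without them is disqualified,
not an error. Both strands, all three frames. Design choices:

- **Stop required** by default: a run without an in-frame stop is not a
  complete translatable frame. `require_stop=False` admits open-ended
  terminal ORFs for sensitivity analyses.
- **codon_count excludes the stop**, so "≥ 30 codons" means ≥ 30 sense codons
  including the ATG — consistent with equating codon counts and peptide
  lengths in amino acids.
- **maximal vs all_starts**: nested qualifying ATGs within one
  (frame, stop) segment cannot be disambiguated from a bare ORF count, so
  the mode is explicit; `maximal` (default) reports the 5′-most start per
  segment, and maximal hits are always a subset of all-starts hits.
- Ambiguous bases (N etc.) inside a candidate ORF reject it (translation
  undefined); minus-strand hits are projected to plus-strand 1-based
  inclusive coordinates with a strand flag, so
  `end − start + 1 = 3·(codon_count + 1)` on either strand.

The scanner is verified, per test run, against a brute-force enumerator that
applies the definition independently at every (strand, position), and against
a strand-symmetry bijection.

## Synthetic data: what it emulates, and what it does not

**Counts.** Negative-binomial counts over 2 species × 5 lines × 3 doses
(0/1/10 µg/mL), with a per-line lognormal random effect (sd 0.3) shared
across a line's conditions — the simplest structure under which pairing is
more powerful than an unpaired comparison, as the paired design assumes. A
chosen fraction of features carries a planted LN-scale treatment effect
(default ln 4) at both nonzero doses and in both species; the
housekeeping feature has effect exactly 0 and sits at the top of the
expression range, mirroring a high, stable *Gapdh*. Defaults — NB size 100
(biological CV 0.1 within a pair, appropriate because pairs are splits of one
culture rather than different animals) and baseline mean counts ln-uniform on
100–10,000 (expressed genes in ~10⁸-read libraries) — were fixed by design
reasoning about the assay, and give the paired *t* at df = 4 high analytic
power for ln(4) effects, consistent with a design that detected hundreds of
DEGs. The real data's dispersion is unknown; these defaults are configurable
and make no claim to match it.

**Repeats.** Lengths follow a log-normal (σ = 0.8) whose 500 bp quantile is
the configured below-500 fraction (default 0.90), truncated to
[50, 9600] bp; this reproduces positive skewness of roughly the reported
3.5–4.5 magnitude and a post-filter median/IQR of the right size. Background
sequence is uniform random ACGT; planted ORFs satisfy the Kozak criteria by
construction and are recorded with strand, plus-strand ATG coordinate and
codon count. Planting does not force the planted ATG to be the 5′-most in
its segment, so recovery checks run in all-starts mode.

Passing tests on these data show the *machinery* is correct and calibrated
under its own assumptions. They do not show anything about multi-mapping
reads, annotation errors, repeat nesting, GC or length biases within a
sample, or real biological dispersion — none of which the generators model.

## Problem sizes and tolerances in the checks

The shipped checks use 10,000 features × both species for null calibration
(type-I at α = 10⁻³ within 3 Monte-Carlo SEs), 5 seeds × 2,000 features for
planted-effect recovery (> 80% recovery, < 0.5% false positives), 1,000
simulated datasets of n = 30 for slope-CI coverage (93–97%), 100 random 2-kb
sequences for scanner–oracle equivalence (exact set equality), TPM column
sums at 10⁻⁶ relative tolerance, and doubling-time inversion at 10⁻⁹
relative error. These sizes make each guarantee statistically meaningful
while keeping a full run in seconds.

## Known limitations

- The GLM-based differential tests used for count matrices elsewhere (edgeR/
  CLC-style) are consumed, not re-derived: only their thresholds are applied.
- Peptide coverage counts unique residues in the union of exact matches;
  published coverage figures can differ slightly under terminal-residue or
  overlap conventions that are not recoverable without the exact reference
  sequence, so unmatched peptides and the per-residue mask are returned for
  inspection.
- Cross-species comparison is symbol-based; orthology beyond shared gene
  symbols is out of scope.
- The ERV length law is a single log-normal; real repeat families are
  mixtures, so tail behaviour beyond the skewness magnitude is not claimed.
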