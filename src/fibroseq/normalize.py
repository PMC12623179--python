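"""The cross-species expression normalization chain.

For within-species paired fold changes and for cross-species comparison,
unique counts are normalized in three ordered steps: (1) by total reads for
the sample (reported here on the counts-per-million scale; the scale cancels
in every downstream ratio), (2) by coding-sequence length as reads per
kilobase, and (3) — for cross-species comparison only — as the ratio to the
housekeeping gene Gapdh in the same sample.  TPM and TMM scaling factors are
provided for the expression-level filter and library-size normalization.

Every product is a :class:`NormalizedMatrix` carrying an ordered provenance
list naming the steps applied, so downstream code can assert it received the
chain it expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "total_count_normalize",
    "per_kb_adjust",
    "gapdh_ratio",
    "tpm",
    "tmm_factors",
    "log_transform",
    "normalize_chain",
]


@dataclass
class NormalizedMatrix:
    """Expression values (features x samples) plus normalization provenance."""

    values: pd.DataFrame
    provenance: list[str]
    samples: pd.DataFrame | None = None
    reference_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must name at least one step")
        if "gapdh-ratio" in self.provenance and self.reference_gene is None:
            raise ValueError("gapdh-ratio provenance requires reference_gene")


def _counts_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def _samples(counts) -> pd.DataFrame | None:
    return counts.samples if isinstance(counts, CountMatrix) else None


def total_count_normalize(counts: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Counts per million: count / sample total x 1e6.

    The 1e6 scale is cosmetic — it cancels in the per-kb and Gapdh-ratio
    steps — but makes intermediate values readable.
    """
    X = _counts_frame(counts)
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[(totals <= 0).to_numpy().argmax()]
        raise ValueError(f"sample {bad!r} has zero total count")
    vals = X.div(totals, axis=1) * 1e6
    return NormalizedMatrix(vals, ["total-count"], samples=_samples(counts))


def per_kb_adjust(norm: NormalizedMatrix, annot: pd.DataFrame) -> NormalizedMatrix:
    """Divide each feature's values by its CDS length in kilobases."""
    missing = norm.values.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"no CDS length for feature(s) {list(missing[:5])}")
    kb = annot.loc[norm.values.index, "cds_length_bp"].astype(float) / 1000.0
    vals = norm.values.div(kb, axis=0)
    return replace(norm, values=vals, provenance=norm.provenance + ["per-kb"])


def gapdh_ratio(norm: NormalizedMatrix, reference: str = "Gapdh") -> NormalizedMatrix:
    """Express every feature as the ratio to the reference (housekeeping)
    gene's value in the same sample.

    The reference row becomes exactly 1 in every sample, which also makes
    the step idempotent on that row.  Between-gene ratios within a sample
    are unchanged.
    """
    if reference not in norm.values.index:
        raise ValueError(f"reference gene {reference!r} not in matrix")
    ref = norm.values.loc[reference]
    if (ref <= 0).any():
        bad = ref.index[(ref <= 0).to_numpy().argmax()]
        raise ValueError(f"reference {reference!r} has non-positive value in sample {bad!r}")
    vals = norm.values.div(ref, axis=1)
    return replace(
        norm,
        values=vals,
        provenance=norm.provenance + ["gapdh-ratio"],
        reference_gene=reference,
    )


def tpm(counts: CountMatrix | pd.DataFrame, annot: pd.DataFrame) -> NormalizedMatrix:
    """Transcripts per million: per-kb read rates rescaled so each sample
    column sums to 1e6."""
    X = _counts_frame(counts)
    missing = X.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"no CDS length for feature(s) {list(missing[:5])}")
    kb = annot.loc[X.index, "cds_length_bp"].astype(float) / 1000.0
    rate = X.div(kb, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum <= 0).any():
        bad = colsum.index[(colsum <= 0).to_numpy().argmax()]
        raise ValueError(f"sample {bad!r} has zero total per-kb rate")
    vals = rate.div(colsum, axis=1) * 1e6
    return NormalizedMatrix(vals, ["tpm"], samples=_samples(counts))


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values library scaling factors.

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean across samples.  For each sample, genes expressed in
    both it and the reference contribute a log2 fold change M and abundance
    A; after trimming 30% of genes on each M tail and 5% on each A tail, the
    factor is 2**(precision-weighted mean of M), with weights from the
    asymptotic (delta-method) variance of M.  Factors are rescaled to have
    geometric mean 1, so they are composition corrections on top of library
    size, not replacements for it: doubling every count in a sample leaves
    its factor at 1.
    """
    X = _counts_frame(counts).astype(float)
    if X.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    frac = X.div(lib, axis=1)
    if ref_sample is None:
        uq = frac.apply(lambda c: np.quantile(c, 0.75))
        ref_sample = (uq - uq.mean()).abs().idxmin()
    r = X[ref_sample].to_numpy()
    nr = lib[ref_sample]

    log_f = {}
    for s in X.columns:
        if s == ref_sample:
            log_f[s] = 0.0
            continue
        x = X[s].to_numpy()
        ns = lib[s]
        keep = (x > 0) & (r > 0)
        if not keep.any():
            raise ValueError(f"sample {s!r} shares no expressed features with reference")
        xs, rs = x[keep], r[keep]
        M = np.log2((xs / ns) / (rs / nr))
        A = 0.5 * np.log2((xs / ns) * (rs / nr))
        # delta-method variance of M for weighting
        v = (ns - xs) / (ns * xs) + (nr - rs) / (nr * rs)
        n = M.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(M)
        ra = rankdata(A)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not sel.any():
            log_f[s] = 0.0
            continue
        f = np.sum(M[sel] / v[sel]) / np.sum(1.0 / v[sel])
        log_f[s] = 0.0 if abs(f) < 1e-6 else f

    factors = pd.Series({s: 2.0 ** f for s, f in log_f.items()})[X.columns]
    factors /= np.exp(np.log(factors).mean())
    return factors


def log_transform(
    norm: NormalizedMatrix | pd.DataFrame,
    base: float | str = "e",
    offset: float = 0.0,
) -> pd.DataFrame:
    """Elementwise log of (value + offset); base 'e', 2 or 10.

    A non-positive argument with zero offset is an error rather than a NaN,
    so silent value loss cannot propagate.
    """
    vals = norm.values if isinstance(norm, NormalizedMatrix) else norm
    shifted = vals + offset
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("log of non-positive value; supply a positive offset")
    out = np.log(shifted)
    if base == 2 or base == "2":
        out = out / np.log(2.0)
    elif base == 10 or base == "10":
        out = out / np.log(10.0)
    elif base not in ("e",):
        raise ValueError(f"unsupported base {base!r}")
    return out


def normalize_chain(
    counts: CountMatrix | pd.DataFrame,
    annot: pd.DataFrame,
    reference: str | None = "Gapdh",
) -> NormalizedMatrix:
    """The full cross-species chain: total-count -> per-kb -> Gapdh ratio.

    With ``reference=None`` the chain stops after the per-kb step (the
    within-species form).
    """
    out = per_kb_adjust(total_count_normalize(counts), annot)
    if reference is not None:
        out = gapdh_ratio(out, reference)
    return out
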