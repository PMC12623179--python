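"""Paired differential expression and cross-species comparison.

The central object is :class:`PairedDEModel`: expression values for one
species, paired within cell line between an agonist dose and the untreated
control.  ``fit()`` returns a :class:`PairedDEResults` with, per feature,
the fold change (geometric mean of the per-line treated/control ratios, so
that ln FC equals the mean of the per-line LN ratios), the two-tailed paired
t-test p-value on the LN ratios, the Benjamini-Hochberg q-value, and the
up/down/none call at the study thresholds (FC >= 2 or <= 0.5 and p < 0.001
by default).

Free functions expose each step (fold change, paired t, BH, calling,
expression filtering, cross-species Gapdh-ratio comparison, the >=10x
species-specificity rule, isoform-reference concordance, Fisher exact and
Kruskal-Wallis) for use outside the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .normalize import NormalizedMatrix, normalize_chain

logger = logging.getLogger("fibroseq")

__all__ = [
    "PairedDEModel",
    "PairedDEResults",
    "paired_fold_change",
    "paired_t",
    "bh_fdr",
    "call_degs",
    "expression_filter",
    "cross_species_ratio",
    "classify_specificity",
    "isoform_concordance",
    "fisher_exact_2x2",
    "kruskal_wallis",
]


def paired_fold_change(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-feature paired fold change across cell lines.

    ``treated`` and ``control`` are features x lines, indexed identically.
    Per line the ratio is (treated + pc) / (control + pc); the fold change
    is the geometric mean of the per-line ratios and ``ln_ratio`` its
    natural log, which therefore equals the mean per-line LN ratio exactly.

    Returns a DataFrame with columns ``fc`` and ``ln_ratio`` plus one
    ``lnr_<line>`` column per line.
    """
    if list(treated.index) != list(control.index):
        raise ValueError("treated and control must share the feature index")
    if list(treated.columns) != list(control.columns):
        raise ValueError("treated and control must be paired on the same cell lines")
    t = treated.to_numpy(dtype=float)
    c = control.to_numpy(dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0:
        if (c == 0).any():
            raise ValueError("zero control value with pseudocount 0")
        if (t == 0).any():
            raise ValueError("zero treated value with pseudocount 0")
    else:
        n_zero = int(((t == 0) | (c == 0)).sum())
        if n_zero:
            logger.info("pseudocount %g applied; %d zero entries", pseudocount, n_zero)
        t = t + pseudocount
        c = c + pseudocount
    lnr = np.log(t) - np.log(c)
    out = pd.DataFrame(index=treated.index)
    out["fc"] = np.exp(lnr.mean(axis=1))
    out["ln_ratio"] = lnr.mean(axis=1)
    for j, line in enumerate(treated.columns):
        out[f"lnr_{line}"] = lnr[:, j]
    return out


def paired_t(ln_ratios) -> float | pd.Series:
    """Two-tailed one-sample t-test of the mean LN ratio against zero.

    Accepts a 1-D array (one feature) or a features x lines DataFrame /
    2-D array.  Zero-variance input yields NaN — an explicit undefined
    flag, never p = 0 — and such features are excluded from FDR ranking.
    """
    if isinstance(ln_ratios, pd.DataFrame):
        arr = ln_ratios.to_numpy(dtype=float)
        res = stats.ttest_1samp(arr, 0.0, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        sd = arr.std(axis=1, ddof=1)
        p[sd == 0] = np.nan
        return pd.Series(p, index=ln_ratios.index, name="p_paired")
    arr = np.asarray(ln_ratios, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need >= 2 paired LN ratios")
    if arr.std(ddof=1) == 0:
        return float("nan")
    return float(stats.ttest_1samp(arr, 0.0).pvalue)


def bh_fdr(pvalues) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.  NaN p-values (the
    zero-variance flag) get NaN q and do not enter the ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q_bh")
    return q


def call_degs(
    records: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    p_max: float = 0.001,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach up/down/none calls at joint fold-change + p thresholds.

    up iff fc >= fc_up and p < p_max; down iff fc <= fc_down and p < p_max
    (boundaries inclusive on FC, strict on p).  Returns the frame with a
    ``call`` column plus the up/down counts.
    """
    fc = records["fc"].to_numpy(dtype=float)
    p = records["p_paired"].to_numpy(dtype=float)
    sig = p < p_max  # NaN compares False: undefined tests are never called
    call = np.where(sig & (fc >= fc_up), "up", np.where(sig & (fc <= fc_down), "down", "none"))
    out = records.copy()
    out["call"] = call
    counts = {"up": int((call == "up").sum()), "down": int((call == "down").sum())}
    return out, counts


def expression_filter(
    tpm_matrix: NormalizedMatrix | pd.DataFrame,
    threshold: float = 10.0,
    scope: str = "any_sample",
) -> pd.Index:
    """Features passing the expression-level filter on TPM.

    ``any_sample`` keeps a feature if its TPM reaches the threshold in at
    least one sample; ``mean`` if its mean TPM over all samples does.
    Boundaries are inclusive.
    """
    if isinstance(tpm_matrix, NormalizedMatrix):
        if "tpm" not in tpm_matrix.provenance:
            logger.warning("expression_filter on matrix without TPM provenance: %s",
                           tpm_matrix.provenance)
        vals = tpm_matrix.values
    else:
        vals = tpm_matrix
    if scope == "any_sample":
        keep = vals.max(axis=1) >= threshold
    elif scope == "mean":
        keep = vals.mean(axis=1) >= threshold
    else:
        raise ValueError("scope must be 'any_sample' or 'mean'")
    return vals.index[keep]


def cross_species_ratio(
    norm_p: pd.DataFrame,
    norm_m: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-species expression ratio on Gapdh-normalized values.

    ``norm_p`` and ``norm_m`` are features x samples for one condition in
    each species, indexed by shared gene symbols.  Genes absent from one
    species are excluded and logged.  Returns, per gene, ``ratio_PM``
    (ratio of species means of the Gapdh-normalized values) and
    ``p_between`` (two-tailed unpaired t on the LN values).
    """
    shared = norm_p.index.intersection(norm_m.index)
    dropped = norm_p.index.symmetric_difference(norm_m.index)
    if len(dropped):
        logger.info("cross_species_ratio: %d genes absent from one species excluded",
                    len(dropped))
    P = norm_p.loc[shared].to_numpy(dtype=float)
    M = norm_m.loc[shared].to_numpy(dtype=float)
    if (P <= 0).any() or (M <= 0).any():
        raise ValueError("cross-species comparison requires positive normalized values")
    res = stats.ttest_ind(np.log(P), np.log(M), axis=1)
    return pd.DataFrame(
        {
            "ratio_PM": P.mean(axis=1) / M.mean(axis=1),
            "p_between": np.asarray(res.pvalue, dtype=float),
        },
        index=shared,
    )


def classify_specificity(fc_p: float, fc_m: float, min_ratio: float = 10.0) -> str:
    """Species-specificity of a response: a >= 10x difference between the
    species' fold changes makes the gene species-specific (boundary
    inclusive); otherwise the response is shared."""
    if not (np.isfinite(fc_p) and np.isfinite(fc_m)) or fc_p <= 0 or fc_m <= 0:
        raise ValueError("fold changes must be finite and positive")
    if fc_p / fc_m >= min_ratio:
        return "P_specific"
    if fc_m / fc_p >= min_ratio:
        return "M_specific"
    return "shared"


def isoform_concordance(calls_1: pd.Series, calls_2: pd.Series) -> pd.DataFrame:
    """Genes whose DEG call differs between two isoform reference sets.

    Both inputs map gene -> call ('up'/'down'/'none') over the same gene
    universe; differing universes are an error listing the symmetric
    difference.  Returns the discordant genes with both calls.
    """
    u1, u2 = set(calls_1.index), set(calls_2.index)
    if u1 != u2:
        raise ValueError(f"gene universes differ: {sorted(u1 ^ u2)[:10]}")
    c2 = calls_2.loc[calls_1.index]
    diff = calls_1 != c2
    return pd.DataFrame({"call_isoform1": calls_1[diff], "call_isoform2": c2[diff]})


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 contingency table: the sum of
    hypergeometric probabilities of tables no more probable than the
    observed one."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def kruskal_wallis(*groups) -> float:
    """Kruskal-Wallis rank test p-value (tie-corrected H, chi-square with
    k-1 df).  All-identical values yield NaN (undefined flag).  Retained
    for two groups as well, where it is a tie-corrected rank test."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if flat.size < 3:
        raise ValueError("need >= 3 observations in total")
    if np.all(flat == flat[0]):
        return float("nan")
    return float(stats.kruskal(*groups).pvalue)


# ---------------------------------------------------------------------------
# model / results


class PairedDEModel:
    """Paired treated-vs-control differential expression for one species.

    Parameters
    ----------
    values
        Normalized expression, features x samples (any chain; the study
        uses total-count -> per-kb, optionally -> Gapdh ratio).
    samples
        Sample metadata in the dataio layout (species, cell_line,
        condition, dose_ug_per_ml).
    species
        Species to analyse; required if ``samples`` holds more than one.
    dose
        Treated dose contrasted against the dose-0 controls (default 1).
    pseudocount
        Added inside the per-line ratio (same scale as ``values``; default
        0).  When building from raw counts use
        :meth:`from_count_matrix`, which instead applies its pseudocount on
        the count scale before normalization, where 0.5 has its usual
        meaning.
    """

    def __init__(
        self,
        values: pd.DataFrame | NormalizedMatrix,
        samples: pd.DataFrame,
        species: str | None = None,
        dose: float = 1.0,
        pseudocount: float = 0.0,
    ) -> None:
        if isinstance(values, NormalizedMatrix):
            values = values.values
        meta = samples
        if species is not None:
            meta = meta[meta["species"] == species]
        elif meta["species"].nunique() > 1:
            raise ValueError("samples span multiple species; pass species=")
        ctrl = meta[meta["dose_ug_per_ml"].astype(float) == 0.0]
        trt = meta[meta["dose_ug_per_ml"].astype(float) == float(dose)]
        lines = sorted(set(ctrl["cell_line"]) & set(trt["cell_line"]))
        if len(lines) < 2:
            raise ValueError(f"need >= 2 paired cell lines, found {len(lines)}")
        ctrl_ids = [ctrl.index[ctrl["cell_line"] == ln][0] for ln in lines]
        trt_ids = [trt.index[trt["cell_line"] == ln][0] for ln in lines]
        self.control = values[ctrl_ids].set_axis(lines, axis=1)
        self.treated = values[trt_ids].set_axis(lines, axis=1)
        self.lines = lines
        self.species = species
        self.dose = dose
        self.pseudocount = pseudocount

    @classmethod
    def from_count_matrix(
        cls,
        counts: CountMatrix,
        annot: pd.DataFrame,
        species: str | None = None,
        dose: float = 1.0,
        reference: str | None = None,
        pseudocount: float = 0.5,
    ) -> "PairedDEModel":
        """Build from raw counts by running the normalization chain
        (total-count -> per-kb, plus the Gapdh ratio if ``reference``).

        ``pseudocount`` is on the count scale and is added to every count
        before normalization only if any zero count is present among the
        samples, so ratios stay defined without distorting well-measured
        features (0.5 on counts of hundreds is <1%).  The application is
        logged.
        """
        X = counts.counts.astype(float)
        if pseudocount > 0 and (X.to_numpy() == 0).any():
            n_zero = int((X.to_numpy() == 0).sum())
            logger.info("count-scale pseudocount %g applied (%d zero counts)",
                        pseudocount, n_zero)
            X = X + pseudocount
        norm = normalize_chain(X, annot, reference=reference)
        return cls(norm.values, counts.samples, species=species, dose=dose,
                   pseudocount=0.0)

    def fit(
        self,
        fc_up: float = 2.0,
        fc_down: float = 0.5,
        p_max: float = 0.001,
    ) -> "PairedDEResults":
        fcs = paired_fold_change(self.treated, self.control, self.pseudocount)
        lnr_cols = [c for c in fcs.columns if c.startswith("lnr_")]
        fcs["p_paired"] = paired_t(fcs[lnr_cols])
        fcs["q_bh"] = bh_fdr(fcs["p_paired"])
        frame, counts = call_degs(fcs, fc_up=fc_up, fc_down=fc_down, p_max=p_max)
        return PairedDEResults(self, frame.drop(columns=lnr_cols), counts,
                               dict(fc_up=fc_up, fc_down=fc_down, p_max=p_max))


@dataclass
class PairedDEResults:
    """Fit results: per-feature FC, LN ratio, paired-t p, BH q and call."""

    model: PairedDEModel
    frame: pd.DataFrame
    counts: dict[str, int]
    thresholds: dict[str, float]

    @property
    def n_up(self) -> int:
        return self.counts["up"]

    @property
    def n_down(self) -> int:
        return self.counts["down"]

    def realized_fdr_at_p(self, p_max: float | None = None) -> float:
        """Largest BH q among features with p below the calling threshold —
        the realized FDR bound the p-criterion implies for this dataset
        (reported rather than hard-coded, since it is dataset-dependent)."""
        p_max = self.thresholds["p_max"] if p_max is None else p_max
        sel = self.frame["p_paired"] < p_max
        if not sel.any():
            return float("nan")
        return float(self.frame.loc[sel, "q_bh"].max())

    def recall(self, fc_up=None, fc_down=None, p_max=None) -> "PairedDEResults":
        """Re-apply calling at different thresholds without refitting."""
        th = dict(self.thresholds)
        for k, v in dict(fc_up=fc_up, fc_down=fc_down, p_max=p_max).items():
            if v is not None:
                th[k] = v
        frame, counts = call_degs(self.frame, **th)
        return PairedDEResults(self.model, frame, counts, th)

    def summary(self) -> str:
        th = self.thresholds
        n = len(self.frame)
        lines = [
            "Paired differential expression",
            "=" * 46,
            f"species:            {self.model.species or 'n/a'}",
            f"dose (ug/mL):       {self.model.dose:g} vs control",
            f"paired cell lines:  {len(self.model.lines)}",
            f"features tested:    {n}",
            f"criteria:           FC >= {th['fc_up']:g} or <= {th['fc_down']:g}, "
            f"p < {th['p_max']:g}",
            f"upregulated DEGs:   {self.n_up}",
            f"downregulated DEGs: {self.n_down}",
            f"realized FDR at p:  {self.realized_fdr_at_p():.4g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="feature_id")
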