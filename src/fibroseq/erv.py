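"""Endogenous-retrovirus / transposable-element expression and length
analyses.

The repeat reference sets are ~1e5 annotated intervals per species with
strongly right-skewed length distributions (~90% of raw records under
500 bp).  The analyses here: the >= 500 bp length filter, Z-scores of
lengths and of mean TPM against their reference distributions, the adjusted
Fisher-Pearson skewness, top-k-by-expression subsets with length summaries,
DEG subsetting at the repeat thresholds, low- vs high-passage contrasts with
signed fold changes, and ordinary least squares of expression on length with
95% confidence (LCL/UCL) and prediction (LPL/UPL) bands.

Statistical conventions documented because the magnitudes depend on them:
sample (n-1) standard deviations throughout; skewness is the adjusted
Fisher-Pearson coefficient (the common spreadsheet/stat-package form);
percentages use half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "filter_min_length",
    "zscore",
    "zscore_lengths",
    "zscore_tpm",
    "skewness",
    "LengthDistributionSummary",
    "top_k_by_tpm",
    "erv_deg_subset",
    "passage_contrast",
    "PassageContrast",
    "ols_with_bands",
    "RegressionFit",
    "percent",
]


def _lengths(records) -> np.ndarray:
    return np.asarray([getattr(r, "length_bp", r) for r in records], dtype=float)


def filter_min_length(records, min_bp: int = 500):
    """Keep records with length >= ``min_bp`` (boundary inclusive).

    Returns ``(kept, excluded_fraction)``; the fraction is NaN for empty
    input.  Idempotent: filtering the kept set again removes nothing.
    """
    records = list(records)
    if not records:
        return [], float("nan")
    lengths = _lengths(records)
    kept = [r for r, L in zip(records, lengths) if L >= min_bp]
    return kept, 1.0 - len(kept) / len(records)


def zscore(query, reference, ddof: int = 1) -> np.ndarray:
    """(x - reference mean) / reference sd, with the sample (n-1) sd."""
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference needs >= 2 values")
    sd = ref.std(ddof=ddof)
    if sd == 0:
        raise ValueError("reference standard deviation is zero")
    return (np.asarray(query, dtype=float) - ref.mean()) / sd


def zscore_lengths(query_lengths, reference_lengths) -> np.ndarray:
    """Length Z-scores against the complete reference set's distribution."""
    return zscore(_lengths(query_lengths), _lengths(reference_lengths))


def zscore_tpm(query_tpm, reference_tpm) -> np.ndarray:
    """Mean-TPM Z-scores against the expressed (TPM-filtered) subset."""
    return zscore(query_tpm, reference_tpm)


def skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment,
    g1 * sqrt(n(n-1))/(n-2).  Constant input yields NaN."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs >= 3 values")
    if x.std(ddof=0) == 0:
        return float("nan")
    return float(stats.skew(x, bias=False))


@dataclass
class LengthDistributionSummary:
    """Summary of a length distribution in bp."""

    n: int
    mean_bp: float
    median_bp: float
    iqr: tuple[float, float]
    skewness: float
    size_class_counts: pd.Series  # histogram over bp bins

    @classmethod
    def from_lengths(cls, lengths, bin_width: int = 500) -> "LengthDistributionSummary":
        x = _lengths(lengths)
        if x.size == 0:
            raise ValueError("no lengths to summarize")
        edge = int(np.ceil(x.max() / bin_width)) * bin_width
        bins = np.arange(0, edge + bin_width, bin_width)
        hist, edges = np.histogram(x, bins=bins)
        labels = [f"{int(a)}-{int(b)}" for a, b in zip(edges[:-1], edges[1:])]
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return cls(
            n=int(x.size),
            mean_bp=float(x.mean()),
            median_bp=float(med),
            iqr=(float(q1), float(q3)),
            skewness=skewness(x) if x.size >= 3 else float("nan"),
            size_class_counts=pd.Series(hist, index=labels, name="count"),
        )


def top_k_by_tpm(table: pd.DataFrame, k: int) -> tuple[pd.DataFrame, LengthDistributionSummary]:
    """The k records of highest mean TPM (e.g. the top ~1% of a reference
    set), with a length summary attached.

    Ties at the k-th rank break deterministically: higher mean TPM, then
    longer length, then lexicographic id.
    """
    if k > len(table):
        raise ValueError(f"k = {k} exceeds table size {len(table)}")
    # mergesort is stable; pre-sorting by id makes the id the final tie-break
    ordered = table.loc[table.index.sort_values()].sort_values(
        by=["mean_tpm", "length_bp"], ascending=[False, False], kind="mergesort"
    )
    top = ordered.head(k)
    return top, LengthDistributionSummary.from_lengths(top["length_bp"].to_numpy())


def erv_deg_subset(
    records: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.001
) -> pd.DataFrame:
    """Repeat elements upregulated at the repeat thresholds: fold change
    >= fc_min (inclusive) and paired-t p < p_max (strict)."""
    keep = (records["fc"] >= fc_min) & (records["p_paired"] < p_max)
    return records[keep]


@dataclass
class PassageContrast:
    """Low- vs high-passage contrast results.

    ``frame`` carries per-feature group means, the signed fold change
    (negative = higher in the second group), p and BH q; ``up`` / ``down``
    are the passing subsets; percentages are of the expressed universe.
    """

    frame: pd.DataFrame
    up: pd.DataFrame
    down: pd.DataFrame
    n_universe: int
    pct_up: float
    pct_down: float

    def summary(self) -> str:
        return (
            f"expressed universe: {self.n_universe}\n"
            f"up in group 1:      {len(self.up)} ({self.pct_up}%)\n"
            f"up in group 2:      {len(self.down)} ({self.pct_down}%)"
        )


def passage_contrast(
    tpm: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    fc_min: float = 4.0,
    tpm_min: float = 10.0,
    q_max: float = 0.01,
    pseudocount: float = 0.5,
    external: pd.DataFrame | None = None,
) -> PassageContrast:
    """Contrast two passage groups of samples (e.g. P4 vs P47).

    Features with mean TPM (over all samples) >= ``tpm_min`` form the
    expressed universe.  Fold change is the ratio of group means, reported
    signed: positive values mean higher in ``group1``, negative values
    denote higher in ``group2``.  Significance is an unpaired two-tailed t
    on ln(TPM + pseudocount) with BH correction; alternatively pass
    ``external`` (feature-indexed columns ``fc_signed`` and ``q``) to apply
    the thresholds to an externally computed FC/FDR table.
    """
    if not group1 or not group2:
        raise ValueError("both groups need >= 1 sample")
    mean_all = tpm.mean(axis=1)
    universe = tpm.index[mean_all >= tpm_min]
    sub = tpm.loc[universe]
    m1 = sub[group1].mean(axis=1)
    m2 = sub[group2].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratio = (m1 + pseudocount) / (m2 + pseudocount)
    fc_signed = np.where(ratio >= 1, ratio, -1.0 / ratio)
    if external is not None:
        ext = external.loc[universe.intersection(external.index)]
        frame = pd.DataFrame(
            {"mean_g1": m1, "mean_g2": m2,
             "fc_signed": ext["fc_signed"], "q": ext["q"]}
        ).dropna(subset=["fc_signed", "q"])
    else:
        lt = np.log(sub[group1].to_numpy(dtype=float) + pseudocount)
        lc = np.log(sub[group2].to_numpy(dtype=float) + pseudocount)
        res = stats.ttest_ind(lt, lc, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        sd_zero = (lt.std(axis=1, ddof=1) == 0) & (lc.std(axis=1, ddof=1) == 0)
        p[sd_zero] = np.nan
        from .diffexpr import bh_fdr  # local import avoids a cycle at module load

        frame = pd.DataFrame(
            {"mean_g1": m1, "mean_g2": m2, "fc_signed": fc_signed,
             "p": p, "q": bh_fdr(p)},
            index=universe,
        )
    passing = (frame["fc_signed"].abs() >= fc_min) & (frame["q"] < q_max)
    up = frame[passing & (frame["fc_signed"] > 0)]
    down = frame[passing & (frame["fc_signed"] < 0)]
    n_u = len(universe)
    return PassageContrast(
        frame=frame, up=up, down=down, n_universe=n_u,
        pct_up=percent(len(up), n_u, 1), pct_down=percent(len(down), n_u, 1),
    )


@dataclass
class RegressionFit:
    """OLS of expression on length with t-based 95% bands.

    ``bands()`` evaluates, at given predictor values, the fitted mean, the
    confidence limits for the conditional mean (LCL/UCL) and the prediction
    limits for a new observation (LPL/UPL); the prediction band strictly
    contains the confidence band at every x.
    """

    slope: float
    intercept: float
    r_squared: float
    level: float
    slope_ci: tuple[float, float]
    _res: object  # statsmodels RegressionResults
    _x: np.ndarray

    def bands(self, x_new=None) -> pd.DataFrame:
        x = self._x if x_new is None else np.asarray(x_new, dtype=float)
        X = sm.add_constant(x, has_constant="add")
        pred = self._res.get_prediction(X)
        sf = pred.summary_frame(alpha=1.0 - self.level)
        return pd.DataFrame(
            {
                "x": x,
                "mean": sf["mean"].to_numpy(),
                "lcl": sf["mean_ci_lower"].to_numpy(),
                "ucl": sf["mean_ci_upper"].to_numpy(),
                "lpl": sf["obs_ci_lower"].to_numpy(),
                "upl": sf["obs_ci_upper"].to_numpy(),
            }
        )

    def summary(self) -> str:
        lo, hi = self.slope_ci
        return (
            f"OLS fit (level {self.level:.0%})\n"
            f"slope:     {self.slope:.6g}  [{lo:.6g}, {hi:.6g}]\n"
            f"intercept: {self.intercept:.6g}\n"
            f"R^2:       {self.r_squared:.4f}"
        )

    def plot(self, ax=None, n_grid: int = 200):
        """Plot the fit with confidence and prediction bands (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(self._x.min(), self._x.max(), n_grid)
        b = self.bands(grid)
        ax.plot(b["x"], b["mean"], label="mean")
        ax.fill_between(b["x"], b["lcl"], b["ucl"], alpha=0.3, label="LCL/UCL")
        ax.plot(b["x"], b["lpl"], "--", label="LPL")
        ax.plot(b["x"], b["upl"], "--", label="UPL")
        ax.legend()
        return ax


def ols_with_bands(x, y, level: float = 0.95, log_y: bool = False) -> RegressionFit:
    """Ordinary least squares of y (mean TPM) on x (length, bp) with
    confidence and prediction bands at ``level``.

    ``log_y=True`` fits ln(y) instead (the band ordering is preserved on
    either scale).  Constant x is an error; n must be >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]):
        raise ValueError("predictor is constant")
    if log_y:
        if (y <= 0).any():
            raise ValueError("log_y requires positive responses")
        y = np.log(y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=1.0 - level)
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        level=level,
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        _res=res,
        _x=x,
    )


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator / denominator with half-up rounding to ``decimals``
    (e.g. 21 of 87 -> 24; 10843 of 103397 -> 10.5)."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))
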