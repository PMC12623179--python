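"""Small self-contained calculators: population doubling time from culture
density series, and MALDI peptide coverage of a protein sequence."""

from __future__ import annotations

import math

import numpy as np
import statsmodels.api as sm

__all__ = ["doubling_time", "peptide_coverage"]


def doubling_time(times_days, densities_per_ml) -> tuple[float, float]:
    """Doubling time (hours) from a log-linear fit of log10 density on time.

    The series is cells/mL at times in days (strictly increasing).  OLS of
    log10(density) against time gives slope b per day; the doubling time is
    24 * log10(2) / b hours.  A non-positive slope (no growth) yields NaN,
    the undefined flag, together with the fit R^2.
    """
    t = np.asarray(times_days, dtype=float)
    d = np.asarray(densities_per_ml, dtype=float)
    if t.size != d.size or t.size < 2:
        raise ValueError("need >= 2 paired observations")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if (d <= 0).any():
        raise ValueError("densities must be positive")
    y = np.log10(d)
    if np.all(y == y[0]):  # no growth at all; R^2 undefined
        return float("nan"), float("nan")
    res = sm.OLS(y, sm.add_constant(t)).fit()
    slope = float(res.params[1])
    r2 = float(res.rsquared) if t.size > 2 else 1.0
    if slope <= 0:
        return float("nan"), r2
    return 24.0 * math.log10(2.0) / slope, r2


def peptide_coverage(protein: str, peptides) -> tuple[float, np.ndarray, list[str]]:
    """Fraction of protein residues covered by exact peptide matches.

    Each peptide is mapped to *all* of its exact-substring occurrences;
    coverage is the size of the union of covered positions over the protein
    length, so overlaps are never double-counted and duplicated peptides
    change nothing.  Returns (fraction, boolean per-residue mask, list of
    peptides with no match).
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    mask = np.zeros(len(protein), dtype=bool)
    unmatched: list[str] = []
    for pep in peptides:
        found = False
        start = protein.find(pep)
        while start != -1:
            mask[start : start + len(pep)] = True
            found = True
            start = protein.find(pep, start + 1)
        if not found:
            unmatched.append(pep)
    return float(mask.sum()) / len(protein), mask, unmatched
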