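"""Synthetic data with the statistical structure the analyses assume.

Two generators:

* :func:`simulate_paired_counts` — negative-binomial count matrices for the
  paired two-species design: 2 species x 5 cell lines x {0, 1, 10} ug/mL
  agonist, one stable housekeeping gene (Gapdh-like, planted treatment
  effect exactly zero), a per-line lognormal random effect shared between a
  line's conditions (so pairing is informative), and a planted LN-scale
  treatment effect on a chosen fraction of features.  A truth table records
  every planted effect.

* :func:`simulate_erv_set` — repeat-element reference sets: ~right-skewed
  (log-normal) lengths with ~90% of raw records under 500 bp, uniform
  random background nucleotides, and Kozak-compliant ORFs planted into a
  chosen fraction of records (purine at -3, ATG, G at +4, >= 30 sense
  codons, in-frame stop), each recorded in a truth table with strand,
  plus-strand coordinates and codon count.

Default magnitudes mirror the study design: five animals per species whose
second-passage cultures are split into the three exposure arms (so the
within-pair residual is small — NB size 100, i.e. a biological CV of 0.1 on
top of counting noise), deep libraries in which expressed features draw
mean counts of hundreds to thousands, and repeat sets whose length law
reproduces positive skewness in the 3.5-4.5 range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import SPECIES, CountMatrix, ErvRecord
from .orf import reverse_complement

__all__ = [
    "CountSimSpec",
    "ErvSimSpec",
    "simulate_paired_counts",
    "simulate_erv_set",
]

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
G_SENSE_CODONS = tuple(c for c in SENSE_CODONS if c[0] == "G")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class CountSimSpec:
    """Parameters of the paired count simulation."""

    n_lines_per_species: int = 5
    doses: tuple[float, ...] = (0.0, 1.0, 10.0)
    n_features: int = 2000
    #: baseline mean count drawn ln-uniform over this range
    baseline_log_mean_range: tuple[float, float] = (math.log(100.0), math.log(10_000.0))
    #: negative-binomial size parameter (1/size = squared biological CV)
    dispersion: float = 100.0
    #: sd of the per-line lognormal random effect shared across conditions
    line_effect_sd: float = 0.3
    frac_deg: float = 0.10
    treatment_ln_effect: float = math.log(4.0)
    species_ln_offset: float = 0.0
    housekeeping_feature: str = "Gapdh"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_deg <= 1.0:
            raise ValueError("frac_deg must lie in [0, 1]")
        if self.n_lines_per_species < 1 or self.n_features < 2:
            raise ValueError("need >= 1 line and >= 2 features")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if 0.0 not in self.doses:
            raise ValueError("doses must include the 0 (control) dose")
        if self.frac_deg > 0 and self.treatment_ln_effect == 0:
            warnings.warn("frac_deg > 0 with treatment_ln_effect = 0: power undefined",
                          stacklevel=2)


def simulate_paired_counts(
    spec: CountSimSpec,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the paired design; returns (counts, annotation, truth).

    The truth table lists each feature's planted LN treatment effect per
    species (identical in both by construction) and a ``is_deg`` flag; the
    housekeeping feature always carries effect exactly 0 and sits at the
    top of the baseline-expression range, as a high, stable expressor.
    """
    rng = np.random.default_rng(spec.seed)
    hk = spec.housekeeping_feature
    feature_ids = [hk] + [f"G{i:06d}" for i in range(1, spec.n_features)]
    lo, hi = spec.baseline_log_mean_range
    base_log = rng.uniform(lo, hi, size=spec.n_features)
    base_log[0] = hi  # housekeeping: high expressor

    n_deg = int(round(spec.frac_deg * (spec.n_features - 1)))
    deg_idx = rng.choice(np.arange(1, spec.n_features), size=n_deg, replace=False)
    effects = np.zeros(spec.n_features)
    effects[deg_idx] = spec.treatment_ln_effect

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for sp in SPECIES:
        sp_off = spec.species_ln_offset if sp == "Pleucopus" else 0.0
        for line_i in range(1, spec.n_lines_per_species + 1):
            line = f"{sp[0]}L{line_i}"
            # shared within the line across conditions -> pairing informative
            line_eff = rng.normal(0.0, spec.line_effect_sd, size=spec.n_features)
            for dose in spec.doses:
                treated = dose > 0
                log_mu = base_log + line_eff + sp_off + (effects if treated else 0.0)
                mu = np.exp(log_mu)
                p = spec.dispersion / (spec.dispersion + mu)
                counts = rng.negative_binomial(spec.dispersion, p)
                sid = f"{sp}_{line}_d{dose:g}"
                cols[sid] = counts
                meta_rows.append(
                    {
                        "sample_id": sid, "species": sp, "cell_line": line,
                        "condition": "agonist" if treated else "control",
                        "dose_ug_per_ml": dose, "passage": 2,
                    }
                )

    counts_df = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    cm = CountMatrix(counts_df, meta)

    cds_len = np.clip(np.exp(rng.normal(7.2, 0.5, size=spec.n_features)), 300, None)
    cds_len = (np.round(cds_len / 3) * 3).astype(int)  # whole codons
    annot = pd.DataFrame(
        {"gene_symbol": feature_ids, "cds_length_bp": cds_len},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    annot.loc[hk, "cds_length_bp"] = 1002

    truth = pd.DataFrame(
        {
            "ln_effect_P": effects,
            "ln_effect_M": effects,
            "is_deg": effects != 0.0,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return cm, annot, truth


@dataclass
class ErvSimSpec:
    """Parameters of the repeat-element sequence simulation."""

    n_records: int = 1000
    frac_below_500: float = 0.90
    #: log-normal sigma of the length law; mu is set so that the 500 bp
    #: quantile matches frac_below_500
    length_log_sd: float = 0.8
    max_length_bp: int = 9600
    min_length_bp: int = 50
    frac_with_planted_orf: float = 0.0
    planted_orf_codons: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_below_500 < 1.0:
            raise ValueError("frac_below_500 must lie in (0, 1)")
        if self.planted_orf_codons < 30:
            raise ValueError("planted ORFs must be >= 30 codons")
        need = self.planted_orf_codons * 3 + 7  # -3..-1 context + ORF + stop + >=1 nt
        if self.frac_with_planted_orf > 0 and need > self.max_length_bp:
            raise ValueError(
                f"planted ORF needs {need} bp, above max_length_bp = {self.max_length_bp}"
            )

    @property
    def length_log_mean(self) -> float:
        return math.log(500.0) - self.length_log_sd * norm.ppf(self.frac_below_500)


def _planted_construct(rng: np.random.Generator, codons: int) -> str:
    """Context + ORF + stop satisfying the Kozak rule by construction."""
    minus3 = rng.choice(list("AG"))
    pad = "".join(rng.choice(list("ACGT"), size=2))
    body = [str(rng.choice(G_SENSE_CODONS))]  # codon 2 starts with G (+4 = G)
    body += [str(c) for c in rng.choice(SENSE_CODONS, size=codons - 2)]
    stop = str(rng.choice(STOP_CODONS))
    return minus3 + pad + "ATG" + "".join(body) + stop


def simulate_erv_set(
    spec: ErvSimSpec,
) -> tuple[list[ErvRecord], pd.DataFrame]:
    """Simulate a repeat reference set; returns (records, truth table).

    Record lengths follow a truncated log-normal whose 500 bp quantile is
    ``frac_below_500``.  Background sequence is uniform random ACGT.  ORFs
    are planted into a random subset of records long enough to hold them
    (on a random strand, at a random in-bounds position); the truth table
    lists parent id, strand, 1-based plus-strand start of the ATG's A, and
    codon count.  Planting does not guarantee the planted ATG is the
    5'-most in its stop segment, so recovery checks use all-starts mode.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sd = spec.length_log_mean, spec.length_log_sd
    lengths = np.empty(spec.n_records, dtype=int)
    filled = 0
    while filled < spec.n_records:
        draw = np.exp(rng.normal(mu, sd, size=spec.n_records))
        ok = draw[(draw >= spec.min_length_bp) & (draw <= spec.max_length_bp)]
        take = min(ok.size, spec.n_records - filled)
        lengths[filled : filled + take] = ok[:take].astype(int)
        filled += take

    need = spec.planted_orf_codons * 3 + 7
    n_plant = int(round(spec.frac_with_planted_orf * spec.n_records))
    long_enough = np.flatnonzero(lengths >= need)
    if n_plant > long_enough.size:
        raise ValueError(
            f"cannot plant {n_plant} ORFs: only {long_enough.size} records "
            f"reach the required {need} bp"
        )
    plant_into = set(rng.choice(long_enough, size=n_plant, replace=False).tolist())

    records: list[ErvRecord] = []
    truth_rows = []
    pos = 0
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(list("ACGT"), size=L))
        if i in plant_into:
            construct = _planted_construct(rng, spec.planted_orf_codons)
            offset = int(rng.integers(0, L - len(construct) + 1))
            strand = str(rng.choice(["+", "-"]))
            ins = construct if strand == "+" else reverse_complement(construct)
            seq = seq[:offset] + ins + seq[offset + len(ins) :]
            if strand == "+":
                atg_start = offset + 3 + 1  # 1-based A of ATG on plus strand
            else:
                # A of ATG is the 4th base of the construct; mirror it
                atg_start = offset + len(construct) - 3
            truth_rows.append(
                {
                    "erv_id": f"ERV{i:06d}", "strand": strand,
                    "atg_start": atg_start,
                    "codon_count": spec.planted_orf_codons,
                }
            )
        records.append(
            ErvRecord(
                erv_id=f"ERV{i:06d}", chrom="chrSim", start=pos, end=pos + int(L),
                strand="+", sequence=seq,
            )
        )
        pos += int(L) + 1000
    truth = pd.DataFrame(
        truth_rows, columns=["erv_id", "strand", "atg_start", "codon_count"]
    )
    return records, truth
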