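"""Readers and writers for the tabular and sequence formats the pipeline touches.

Conventions
-----------
* All tables are TSV with a header row; decimal point ``.``, no thousands
  separators.
* Counts are unique-read integers.  Fractional values (e.g. from fractional
  multi-mapper allocation) are rejected, never silently rounded.
* Repeat-element intervals are stored zero-based, end-exclusive, so
  ``length_bp == end - start``; one-based inclusive input is converted with
  ``one_based=True``.
* FASTA sequences are uppercased on read; record ids are the first
  whitespace-delimited token of the header line.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fibroseq")

SPECIES = ("Pleucopus", "Mmusculus")
CONDITIONS = ("control", "agonist")

#: IUPAC nucleotide alphabet (uppercase) accepted in FASTA input.
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")

SAMPLE_COLUMNS = ("species", "cell_line", "condition", "dose_ug_per_ml", "passage")


class FormatError(ValueError):
    """Raised when an input file violates the documented layout."""


@dataclass
class CountMatrix:
    """Unique-read counts (features x samples) with per-sample metadata.

    ``counts`` is an integer DataFrame indexed by feature id with one column
    per sample; ``samples`` is indexed by sample id and carries species,
    cell line (which pairs samples across conditions), condition, dose and
    passage.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.samples.index if s not in self.counts.columns]
        if extra:
            raise FormatError(f"metadata rows without a matrix column: {extra}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise FormatError(f"metadata lacks required column {col!r}")
        bad_sp = set(self.samples["species"]) - set(SPECIES)
        if bad_sp:
            raise FormatError(f"unknown species {sorted(bad_sp)}; expected {SPECIES}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown condition {sorted(bad_cond)}; expected {CONDITIONS}")
        if (self.samples["dose_ug_per_ml"].astype(float) < 0).any():
            raise FormatError("negative dose in metadata")
        key = self.samples[["species", "cell_line", "condition", "dose_ug_per_ml"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise FormatError(
                "duplicate (species, cell_line, condition, dose) sample: "
                f"{tuple(dup)}"
            )
        # every cell line needs an untreated control so pairing is defined
        for (sp, line), grp in self.samples.groupby(["species", "cell_line"]):
            if not ((grp["condition"] == "control")).any():
                raise FormatError(f"cell line {line!r} ({sp}) has no control sample")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("negative count")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, species: str | None = None, dose: float | None = None) -> list[str]:
        """Sample ids restricted to a species and/or dose."""
        meta = self.samples
        keep = pd.Series(True, index=meta.index)
        if species is not None:
            keep &= meta["species"] == species
        if dose is not None:
            keep &= meta["dose_ug_per_ml"].astype(float) == float(dose)
        return list(meta.index[keep])


@dataclass(frozen=True)
class ErvRecord:
    """One annotated repeat element (ERV/TE) interval, end-exclusive."""

    erv_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"{self.erv_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise FormatError(f"{self.erv_id}: negative start")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.erv_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise FormatError(
                f"{self.erv_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.length_bp}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a feature-by-sample count TSV plus its sample-metadata TSV.

    The matrix header row carries sample ids and the first column feature
    ids.  Counts must be non-negative integers; a fractional value is a hard
    error naming the offending cell, and a sample absent from the metadata is
    a hard error naming the sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        num = pd.to_numeric(raw[col], errors="coerce")
        if num.isna().any():
            feat = raw.index[num.isna().to_numpy().argmax()]
            raise FormatError(f"non-numeric count at feature {feat!r}, sample {col!r}")
        if (np.mod(num, 1) != 0).any():
            feat = raw.index[(np.mod(num, 1) != 0).to_numpy().argmax()]
            raise FormatError(
                f"non-integer count {num.loc[feat]!r} at feature {feat!r}, sample {col!r}"
            )
        counts[col] = num.astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")
    cm.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Feature annotation TSV: feature_id, gene_symbol, cds_length_bp."""
    annot = pd.read_csv(path, sep="\t", index_col=0)
    if "cds_length_bp" not in annot.columns:
        raise FormatError("annotation lacks 'cds_length_bp' column")
    if (annot["cds_length_bp"] < 3).any():
        feat = annot.index[(annot["cds_length_bp"] < 3).to_numpy().argmax()]
        raise FormatError(f"cds_length_bp < 3 for feature {feat!r}")
    if not annot.index.is_unique:
        raise FormatError("duplicate feature ids in annotation")
    return annot


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse nucleotide FASTA into ``(id, uppercased sequence)`` pairs.

    Arbitrary line wrapping is accepted.  An empty record or a non-IUPAC
    character is a hard error naming the record (and position).
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {name!r}")
        for i, base in enumerate(seq):
            if base not in IUPAC_NT:
                raise FormatError(
                    f"record {name!r}: non-IUPAC character {base!r} at position {i + 1}"
                )
        records.append((name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError("FASTA header with empty id")
                chunks = []
            else:
                if name is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
        flush()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# canonical ERV table layout; a column-mapping dict adapts other layouts
ERV_COLUMNS = {"erv_id": "erv_id", "chrom": "chrom", "start": "start",
               "end": "end", "strand": "strand"}


def read_erv_table(
    path: str | Path,
    one_based: bool = False,
    column_map: dict[str, str] | None = None,
) -> list[ErvRecord]:
    """Read a repeat-element interval TSV into :class:`ErvRecord` objects.

    Lengths are computed as ``end - start`` (end-exclusive).  With
    ``one_based=True`` the input is interpreted as one-based inclusive and
    converted (start decremented).  If the table carries its own length
    column it must agree with the computed length; disagreement rejects the
    record.
    """
    cols = dict(ERV_COLUMNS)
    if column_map:
        cols.update(column_map)
    tab = pd.read_csv(path, sep="\t")
    for want in cols.values():
        if want not in tab.columns:
            raise FormatError(f"ERV table lacks column {want!r}")
    records = []
    for _, row in tab.iterrows():
        start = int(row[cols["start"]])
        end = int(row[cols["end"]])
        if one_based:
            start -= 1
        rec = ErvRecord(
            erv_id=str(row[cols["erv_id"]]),
            chrom=str(row[cols["chrom"]]),
            start=start,
            end=end,
            strand=str(row[cols["strand"]]),
            sequence=(str(row["sequence"]) if "sequence" in tab.columns
                      and pd.notna(row.get("sequence")) else None),
        )
        if "length_bp" in tab.columns and pd.notna(row["length_bp"]):
            if int(row["length_bp"]) != rec.length_bp:
                raise FormatError(
                    f"{rec.erv_id}: stated length {int(row['length_bp'])} "
                    f"disagrees with end - start = {rec.length_bp}"
                )
        records.append(rec)
    return records


def write_erv_table(records: Sequence[ErvRecord], path: str | Path) -> None:
    rows = [
        {
            "erv_id": r.erv_id, "chrom": r.chrom, "start": r.start, "end": r.end,
            "strand": r.strand, "length_bp": r.length_bp,
            "sequence": r.sequence if r.sequence is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """YAML run configuration (seed, thresholds, paths)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("run config must be a YAML mapping")
    return cfg


@contextmanager
def stage(name: str):
    """Log a pipeline stage with wall-clock timing to stderr."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    t0 = time.perf_counter()
    logger.info("%s: started", name)
    yield
    logger.info("%s: done in %.2f s", name, time.perf_counter() - t0)
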