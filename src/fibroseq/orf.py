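"""Kozak-context open-reading-frame scanning and translation.

An ORF qualifies when it starts at an ATG (the A is position +1), runs at
least 30 codons to the first in-frame stop wholly inside the sequence, and
sits in a favourable translation-initiation context: a purine (A or G) at
position -3 and a G at position +4.  Position +4 is the first base of the
second codon, so it always lies inside the ORF; position -3 requires at
least three bases upstream of the ATG on the scanned strand — an ATG closer
than that to the 5' end is disqualified, not an error.

Both strands are scanned in all three frames.  Minus-strand hits are
projected onto plus-strand coordinates (1-based, inclusive, footprint
including the stop codon) with a strand flag, so hits can be rendered as
standard annotation intervals.  ``mode='maximal'`` reports only the 5'-most
qualifying ATG per (strand, frame, stop) segment; ``mode='all_starts'``
reports every qualifying ATG, so maximal-mode hits are always a subset.

Whether a stop codon is required inside the sequence is a flag
(``require_stop``, default True): a run without an in-frame stop is not a
complete, translatable frame under the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "OrfHit",
    "reverse_complement",
    "find_kozak_orfs",
    "translate",
    "orf_length_summary",
]

PURINES = frozenset("AG")
STOPS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)
_VALID = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class OrfHit:
    """One qualifying ORF.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates of the
    full footprint including the stop codon, so
    ``end - start + 1 == 3 * (codon_count + 1)`` on either strand.
    ``codon_count`` counts sense codons from the ATG through the last codon
    before the stop; the peptide has exactly that many residues.
    """

    parent_id: str
    strand: str
    start: int
    end: int
    codon_count: int
    minus3_base: str
    plus4_base: str
    peptide: str


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity codes (N -> N)."""
    for i, ch in enumerate(seq.upper()):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i + 1}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(cds: str, include_stop_check: bool = False) -> str:
    """Translate a CDS with the standard genetic code, one letter per codon.

    A terminal stop, when present, is excluded from the reported peptide.
    With ``include_stop_check`` an internal stop is an error naming the
    codon index (1-based).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if include_stop_check and "*" in aa:
        raise ValueError(f"internal stop at codon {aa.index('*') + 1}")
    return aa


def _scan_strand(s: str, min_codons: int, mode: str, require_stop: bool):
    """Yield (start0, stop_end0_exclusive, codon_count, minus3, plus4) hits
    on the given strand sequence, coordinates local to that strand."""
    L = len(s)
    for frame in range(3):
        # codon boundaries for this frame
        stops = [i for i in range(frame, L - 2, 3) if s[i : i + 3] in STOPS]
        seg_start = frame
        for stop in stops + [None]:
            seg_end = stop if stop is not None else None
            if seg_end is None and require_stop:
                break
            # candidate ATGs between seg_start and the stop (exclusive)
            limit = seg_end if seg_end is not None else L - 2
            for p in range(seg_start, limit, 3):
                if s[p : p + 3] != "ATG":
                    continue
                if p < 3:
                    continue  # fewer than 3 upstream bases: disqualified
                minus3 = s[p - 3]
                if minus3 not in PURINES:
                    continue
                if p + 3 >= L:
                    continue
                plus4 = s[p + 3]
                if plus4 != "G":
                    continue
                if seg_end is not None:
                    codon_count = (seg_end - p) // 3
                    orf_end = seg_end + 3  # include the stop codon
                else:
                    codon_count = (L - p) // 3
                    orf_end = p + codon_count * 3
                if codon_count < min_codons:
                    continue
                body = s[p : p + codon_count * 3]
                if any(b not in "ACGT" for b in body):
                    continue  # ambiguous base inside ORF: translation undefined
                yield (p, orf_end, codon_count, minus3, plus4)
                if mode == "maximal":
                    break
            if seg_end is not None:
                seg_start = seg_end + 3


def find_kozak_orfs(
    seq: str,
    min_codons: int = 30,
    mode: str = "maximal",
    require_stop: bool = True,
    parent_id: str = "",
) -> list[OrfHit]:
    """Scan both strands, all three frames, for Kozak-context ORFs."""
    if mode not in ("maximal", "all_starts"):
        raise ValueError("mode must be 'maximal' or 'all_starts'")
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    s = seq.upper()
    L = len(s)
    if L < min_codons * 3 + 3:
        raise ValueError(
            f"sequence length {L} below minimum {min_codons * 3 + 3} "
            f"for {min_codons}-codon ORFs with a stop"
        )
    hits: list[OrfHit] = []
    for strand, strand_seq in (("+", s), ("-", reverse_complement(s))):
        for p0, end0, cc, m3, p4 in _scan_strand(strand_seq, min_codons, mode, require_stop):
            body = strand_seq[p0 : p0 + cc * 3]
            peptide = translate(body)
            if strand == "+":
                start, end = p0 + 1, end0
            else:
                # mirror local [p0+1, end0] onto plus-strand coordinates
                start, end = L - end0 + 1, L - p0
            hits.append(
                OrfHit(
                    parent_id=parent_id, strand=strand, start=start, end=end,
                    codon_count=cc, minus3_base=m3, plus4_base=p4, peptide=peptide,
                )
            )
    hits.sort(key=lambda h: (h.strand, h.start, h.end))
    return hits


def orf_length_summary(hits, n_parents: int | None = None) -> dict:
    """Summary of peptide lengths (aa): mean with 95% t-interval, range,
    per-parent counts, and — given ``n_parents`` — the fraction of parents
    with at least one hit.  Empty input yields NaN fields."""
    hits = list(hits)
    if not hits:
        return {
            "n": 0, "mean_aa": float("nan"), "ci95": (float("nan"), float("nan")),
            "range_aa": (float("nan"), float("nan")), "per_parent": {},
            "fraction_parents_with_hit": float("nan"),
        }
    lengths = np.array([h.codon_count for h in hits], dtype=float)
    mean = float(lengths.mean())
    if lengths.size > 1 and lengths.std(ddof=1) > 0:
        sem = lengths.std(ddof=1) / np.sqrt(lengths.size)
        tcrit = stats.t.ppf(0.975, lengths.size - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
    else:
        ci = (mean, mean)
    per_parent: dict[str, int] = {}
    for h in hits:
        per_parent[h.parent_id] = per_parent.get(h.parent_id, 0) + 1
    frac = (len(per_parent) / n_parents) if n_parents else float("nan")
    return {
        "n": int(lengths.size),
        "mean_aa": mean,
        "ci95": (float(ci[0]), float(ci[1])),
        "range_aa": (float(lengths.min()), float(lengths.max())),
        "per_parent": per_parent,
        "fraction_parents_with_hit": frac,
    }
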