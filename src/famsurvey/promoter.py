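"""Promoter scanning for degenerate cis-regulatory elements.

Motifs are IUPAC nucleotide patterns (PLACE-style). Both strands of each
promoter are scanned; a minus-strand hit is reported at the 1-based position
of the match start on the plus strand. Overlapping matches are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

IUPAC: Dict[str, Set[str]] = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    """Invalid IUPAC pattern or promoter sequence."""


@dataclass
class MotifHit:
    promoter_id: str
    motif_name: str
    strand: str          # + or -
    position: int        # 1-based offset of the match start on the + strand
    matched_sequence: str  # promoter bases on the + strand at the match window


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise MotifError(f"invalid IUPAC codes {sorted(bad)} in pattern {pattern!r}")
    return pattern


def _matches_at(seq: str, pattern: str, i: int) -> bool:
    for k, code in enumerate(pattern):
        base = seq[i + k]
        if base == "N" or base not in IUPAC[code]:
            # an N in the promoter never satisfies a motif position
            return False
    return True


def scan_promoter(
    promoter_id: str,
    sequence: str,
    motifs: Iterable[Tuple[str, str]],
) -> List[MotifHit]:
    """Report every match of each IUPAC motif on either strand of a promoter.

    ``motifs`` yields (name, pattern) pairs. Plus-strand hits match the
    sequence directly; minus-strand hits are positions whose plus-strand
    window equals the reverse complement of the pattern's match.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise MotifError(f"promoter {promoter_id!r}: illegal bases {sorted(bad)}")
    hits: List[MotifHit] = []
    for name, pattern in motifs:
        pattern = _validate_pattern(pattern)
        L = len(pattern)
        if L == 0 or L > len(seq):
            continue
        rc_pattern = "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
             "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
             "D": "H", "H": "D", "N": "N"}[c] for c in reversed(pattern)
        )
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if _matches_at(seq, pattern, i):
                hits.append(MotifHit(promoter_id, name, "+", i + 1, window))
            if _matches_at(seq, rc_pattern, i):
                hits.append(MotifHit(promoter_id, name, "-", i + 1, window))
    hits.sort(key=lambda h: (h.motif_name, h.position, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str], motif_library: pd.DataFrame
) -> List[MotifHit]:
    motifs = list(zip(motif_library["name"], motif_library["pattern"]))
    hits: List[MotifHit] = []
    for pid in sorted(promoters):
        hits.extend(scan_promoter(pid, promoters[pid], motifs))
    return hits


def element_presence_table(
    members: Sequence[str],
    hits: Iterable[MotifHit],
    motif_library: pd.DataFrame,
) -> pd.DataFrame:
    """Gene × motif table of hit counts; "NF" marks motifs not found."""
    motif_names = list(motif_library["name"])
    counts: Dict[Tuple[str, str], int] = {}
    for h in hits:
        counts[(h.promoter_id, h.motif_name)] = counts.get(
            (h.promoter_id, h.motif_name), 0
        ) + 1
    table = pd.DataFrame(
        [
            [counts.get((g, m), 0) or "NF" for m in motif_names]
            for g in members
        ],
        index=list(members),
        columns=motif_names,
    )
    table.index.name = "gene_id"
    return table
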