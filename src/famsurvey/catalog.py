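"""Family membership, subfamily classification and protein physicochemistry.

A family member is a locus whose representative (longest) protein carries at
least one WD40 domain annotation from an external scanner table (SMART/Pfam
dialect), or — for self-contained testing — at least one GH…WD repeat found by
the built-in detector. The built-in detector is a deliberately simple
dipeptide-anchor rule and is *not* equivalent to profile-HMM domain scanning.

Subfamilies A..K partition members by the non-WD40 domains they carry.
Physicochemical properties (molecular weight, theoretical pI, instability
index) follow the classic ProtParam definitions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV  # published dipeptide instability weights

from .io import DomainHit, GeneModel, _natural_key

WATER_MW = 18.0153

#: Average residue masses (free amino-acid mass minus one water).
RESIDUE_MASS: Dict[str, float] = {
    aa: mw - WATER_MW for aa, mw in protein_weights.items()
}
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

#: ProtParam-compatible pKa set (Bjellqvist-style side-chain and terminal
#: values). Configurable: pass an alternative mapping to net_charge/isoelectric_point.
PKA_POSITIVE: Dict[str, float] = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE: Dict[str, float] = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

FAMILY_DOMAIN = "WD40"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SequenceError(ValueError):
    """Illegal or degenerate protein sequence input."""


# ---------------------------------------------------------------------------
# GH...WD repeat detector
# ---------------------------------------------------------------------------

def scan_wd40_repeats(sequence: str, min_sep: int = 20, max_sep: int = 50) -> List[Tuple[int, int]]:
    """Locate GH…WD repeat units in an amino-acid sequence.

    A unit runs from a ``GH`` dipeptide to the first downstream ``WD`` whose
    separation (residues strictly between the H and the W) lies within
    ``[min_sep, max_sep]`` — the ~40-residue repeat core. Units are taken
    greedily left to right and do not overlap. Spans are 1-based inclusive.
    """
    seq = sequence.upper()
    illegal = set(seq) - set(AA20 + "X")
    if illegal:
        raise SequenceError(f"illegal residues {sorted(illegal)}")
    spans: List[Tuple[int, int]] = []
    pos = 0  # 0-based index from which to search for the next GH
    n = len(seq)
    while True:
        g = seq.find("GH", pos)
        if g == -1:
            break
        h = g + 1  # index of H
        found = None
        for w in range(h + 1 + min_sep, min(h + 1 + max_sep, n - 2) + 1):
            if seq[w] == "W" and seq[w + 1] == "D":
                found = w
                break
        if found is None:
            pos = g + 1
            continue
        spans.append((g + 1, found + 2))  # 1-based, inclusive of the D
        pos = found + 2  # restart after the consumed WD
    return spans


# ---------------------------------------------------------------------------
# representative transcript
# ---------------------------------------------------------------------------

def select_representative(transcripts: Mapping[str, int]) -> str:
    """Pick the representative transcript of a locus.

    ``transcripts`` maps transcript/protein id to protein length (aa). Returns
    the longest; ties break to the lexicographically smallest id.
    """
    if not transcripts:
        raise ValueError("locus has no transcripts")
    return min(transcripts, key=lambda t: (-transcripts[t], t))


# ---------------------------------------------------------------------------
# subfamily classification
# ---------------------------------------------------------------------------

def _is_zinc_finger(name: str) -> bool:
    low = name.lower()
    return low.startswith("zf") or "zinc" in low or low.startswith("znf")


_SUBFAMILY_RULES: List[Tuple[str, object]] = [
    ("B", {"LisH"}),
    ("C", {"Utp12", "Utp13", "Utp15", "Utp21"}),
    ("D", {"WDAD", "COPI-alpha-C"}),
    ("E", {"RBBP4", "CAF1-C"}),
    ("F", {"NLE"}),
    ("G", {"Pkinase", "HEAT"}),
    ("H", {"BEACH"}),
    ("I", _is_zinc_finger),
    ("J", {"BCAS3"}),
]


def classify_subfamily(domains: Set[str], with_ambiguity: bool = False):
    """Assign a subfamily label A..K from a protein's domain composition.

    Rules are evaluated in order B…J, then K (any other non-WD40 domain), then
    A (WD40 only). When more than one diagnostic rule fires the first wins and
    the ambiguity flag is set.
    """
    if FAMILY_DOMAIN not in domains:
        raise ValueError("domain set lacks the family WD40 domain")
    extra = {d for d in domains if d != FAMILY_DOMAIN}
    fired = []
    matched_by_rules: Set[str] = set()
    for label, rule in _SUBFAMILY_RULES:
        if callable(rule):
            hit = {d for d in extra if rule(d)}
        else:
            hit = extra & rule
        if hit:
            fired.append(label)
            matched_by_rules |= hit
    if fired:
        label = fired[0]
        ambiguous = len(fired) > 1
    elif extra:
        label, ambiguous = "K", False
    else:
        label, ambiguous = "A", False
    return (label, ambiguous) if with_ambiguity else label


# ---------------------------------------------------------------------------
# physicochemical properties
# ---------------------------------------------------------------------------

def molecular_weight(sequence: str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water.

    ``X`` contributes the mean of the twenty standard residue masses.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    total = WATER_MW
    for aa in sequence.upper():
        if aa == "X":
            total += _MEAN_RESIDUE_MASS
        elif aa in RESIDUE_MASS:
            total += RESIDUE_MASS[aa]
        else:
            raise SequenceError(f"unknown residue {aa!r}")
    return total


def net_charge(
    sequence: str,
    pH: float,
    pka_positive: Mapping[str, float] = PKA_POSITIVE,
    pka_negative: Mapping[str, float] = PKA_NEGATIVE,
) -> float:
    """Model net charge at a given pH (Henderson–Hasselbalch per group).

    ``X`` residues contribute no side-chain charge; the termini always do.
    """
    seq = sequence.upper()
    charge = 1.0 / (1.0 + 10 ** (pH - pka_positive["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka_negative["Cterm"] - pH))
    for aa in seq:
        if aa in pka_positive:
            charge += 1.0 / (1.0 + 10 ** (pH - pka_positive[aa]))
        elif aa in pka_negative:
            charge -= 1.0 / (1.0 + 10 ** (pka_negative[aa] - pH))
    return charge


def isoelectric_point(
    sequence: str,
    tol: float = 1e-4,
    pka_positive: Mapping[str, float] = PKA_POSITIVE,
    pka_negative: Mapping[str, float] = PKA_NEGATIVE,
) -> float:
    """Theoretical pI: the pH at which the modeled net charge vanishes.

    Found by bisection on [0, 14] down to |charge| < ``tol``. The charge
    function is strictly decreasing in pH, so the root is unique.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(sequence, mid, pka_positive, pka_negative)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(sequence: str) -> float:
    """ProtParam instability index: (10/L) · Σ DIWV(aa_i, aa_{i+1}).

    Dipeptides involving ``X`` contribute zero weight. Sequences shorter than
    two residues have no dipeptide and raise.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise SequenceError("instability index undefined for length < 2")
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        if a == "X" or b == "X":
            continue
        try:
            total += DIWV[a][b]
        except KeyError as exc:
            raise SequenceError(f"unknown residue in dipeptide {a}{b}") from exc
    return total * 10.0 / len(seq)


def protein_properties(sequence: str) -> Tuple[int, float, float, float, bool]:
    """(length, molecular weight Da, pI, instability index, stable).

    A protein is called stable when its instability index is ≤ 40.
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceError("empty sequence")
    ii = instability_index(seq)
    return (len(seq), molecular_weight(seq), isoelectric_point(seq), ii, ii <= 40.0)


# ---------------------------------------------------------------------------
# catalog assembly
# ---------------------------------------------------------------------------

@dataclass
class FamilyMember:
    """One named family locus with its classification and protein properties."""

    name: str
    gene_id: str
    representative_protein_id: str
    repeat_hits: List[Tuple[int, int]]
    subfamily: str
    ambiguous: bool
    length: int
    molecular_weight: float
    pI: float
    instability_index: float
    stable: bool
    chromosome: str
    start: int
    end: int


def build_catalog(
    gene_models: Sequence[GeneModel],
    proteins: Mapping[str, str],
    domain_hits: Iterable[DomainHit],
    builtin_detector: bool = False,
    min_repeats: int = 1,
    name_prefix: str = "FAM",
) -> List[FamilyMember]:
    """Identify family members and assemble the ordinal catalog.

    ``proteins`` maps protein/transcript id to amino-acid sequence. Membership:
    the locus representative protein carries ≥1 WD40 hit of source smart/pfam
    in ``domain_hits``, or (``builtin_detector``) ≥ ``min_repeats`` GH…WD
    spans. Members are named ``{prefix}-1..n`` by chromosome natural order and
    start coordinate.
    """
    hits_by_protein: Dict[str, List[DomainHit]] = {}
    for h in domain_hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)

    members: List[FamilyMember] = []
    ordered = sorted(gene_models, key=lambda m: (_natural_key(m.chromosome), m.start))
    for model in ordered:
        if not model.transcripts:
            continue
        lengths = dict(model.transcripts)
        rep = select_representative(lengths)
        if rep not in proteins:
            raise ValueError(f"no protein sequence for representative {rep!r} of {model.gene_id}")
        seq = proteins[rep]
        hits = hits_by_protein.get(rep, [])
        wd_hits = [
            h for h in hits
            if h.domain_name == FAMILY_DOMAIN and h.source in {"smart", "pfam"}
        ]
        repeat_spans = [(h.start, h.end) for h in sorted(wd_hits, key=lambda h: h.start)]
        is_member = bool(wd_hits)
        if not is_member and builtin_detector:
            repeat_spans = scan_wd40_repeats(seq)
            is_member = len(repeat_spans) >= min_repeats
        if not is_member:
            continue
        domains = {h.domain_name for h in hits} | {FAMILY_DOMAIN}
        subfamily, ambiguous = classify_subfamily(domains, with_ambiguity=True)
        length, mw, pi, ii, stable = protein_properties(seq)
        members.append(
            FamilyMember(
                name="",  # assigned below once ordering is final
                gene_id=model.gene_id,
                representative_protein_id=rep,
                repeat_hits=repeat_spans,
                subfamily=subfamily,
                ambiguous=ambiguous,
                length=length,
                molecular_weight=mw,
                pI=pi,
                instability_index=ii,
                stable=stable,
                chromosome=model.chromosome,
                start=model.start,
                end=model.end,
            )
        )
    for i, m in enumerate(members, 1):
        m.name = f"{name_prefix}-{i}"
    return members


def catalog_table(members: Sequence[FamilyMember]):
    """Catalog as a DataFrame (name, locus, coordinates, properties, subfamily)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": m.name,
                "gene_id": m.gene_id,
                "protein_id": m.representative_protein_id,
                "chromosome": m.chromosome,
                "start": m.start,
                "end": m.end,
                "length_aa": m.length,
                "molecular_weight": round(m.molecular_weight, 2),
                "pI": round(m.pI, 4),
                "instability_index": round(m.instability_index, 2),
                "stable": m.stable,
                "subfamily": m.subfamily,
                "ambiguous": m.ambiguous,
            }
            for m in members
        ]
    )
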