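"""Classification of family expansion events: tandem and segmental duplication.

Tandem duplicates are family genes separated by at most ``max_intervening``
(default 5) annotated genes on the same chromosome, grouped as connected
components of that relation. Segmental duplicates are family genes assignable
to precomputed collinear duplication blocks within a maximal anchor offset
(default 500 kb). Protein similarity of duplicate pairs is measured by global
(Needleman–Wunsch) alignment identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import GeneModel, _natural_key


@dataclass
class TandemGroup:
    group_id: str
    members: List[str]                 # gene ids ordered by start
    intervening: List[int]             # genes between consecutive members
    gaps_bp: List[int]                 # bp between consecutive member spans


@dataclass
class SegmentalPair:
    gene_a: str
    gene_b: str
    block_id: str
    offset_bp: int                     # larger of the two gene→anchor offsets
    identity_pct: Optional[float] = None


def pair_distance(model_a: GeneModel, model_b: GeneModel) -> int:
    """Gap in bp between two gene spans on the same chromosome.

    Overlapping or juxtaposed spans give 0.
    """
    if model_a.chromosome != model_b.chromosome:
        raise ValueError(
            f"{model_a.gene_id} and {model_b.gene_id} lie on different chromosomes"
        )
    first, second = sorted((model_a, model_b), key=lambda m: m.start)
    return max(0, second.start - first.end - 1)


def find_tandem_groups(
    family_genes: Sequence[str],
    gene_models: Sequence[GeneModel],
    max_intervening: int = 5,
) -> List[TandemGroup]:
    """Group tandemly duplicated family genes.

    Two family genes are linked when they share a chromosome and at most
    ``max_intervening`` annotated genes (family or not) lie between them in
    positional order. Groups are connected components of this relation;
    singletons are not reported.
    """
    by_id = {m.gene_id: m for m in gene_models}
    missing = [g for g in family_genes if g not in by_id]
    if missing:
        raise ValueError(f"family genes absent from gene models: {missing}")

    # positional index per chromosome
    by_chrom: Dict[str, List[GeneModel]] = {}
    for m in sorted(gene_models, key=lambda m: (_natural_key(m.chromosome), m.start)):
        by_chrom.setdefault(m.chromosome, []).append(m)
    position = {
        m.gene_id: i for models in by_chrom.values() for i, m in enumerate(models)
    }

    fam = set(family_genes)
    groups: List[TandemGroup] = []
    counter = 0
    for chrom, models in sorted(by_chrom.items(), key=lambda kv: _natural_key(kv[0])):
        fam_here = [m for m in models if m.gene_id in fam]
        # chain consecutive family genes whose positional gap is small enough
        current: List[GeneModel] = []
        runs: List[List[GeneModel]] = []
        for m in fam_here:
            if current and position[m.gene_id] - position[current[-1].gene_id] - 1 <= max_intervening:
                current.append(m)
            else:
                if len(current) > 1:
                    runs.append(current)
                current = [m]
        if len(current) > 1:
            runs.append(current)
        for run in runs:
            counter += 1
            groups.append(
                TandemGroup(
                    group_id=f"TG{counter}",
                    members=[m.gene_id for m in run],
                    intervening=[
                        position[b.gene_id] - position[a.gene_id] - 1
                        for a, b in zip(run, run[1:])
                    ],
                    gaps_bp=[pair_distance(a, b) for a, b in zip(run, run[1:])],
                )
            )
    return groups


def _span_offset(start: int, end: int, anchor_start: int, anchor_end: int) -> int:
    """bp distance between a gene span and a block anchor span (0 if overlapping)."""
    if end < anchor_start:
        return anchor_start - end - 1
    if anchor_end < start:
        return start - anchor_end - 1
    return 0


def assign_segmental_pairs(
    family_genes: Sequence[str],
    gene_models: Sequence[GeneModel],
    blocks: pd.DataFrame,
    max_offset: int = 500_000,
) -> List[SegmentalPair]:
    """Assign family genes to segmental duplication blocks.

    ``blocks`` rows give (block_id, chrA, startA, endA, chrB, startB, endB).
    For each block the nearest family gene within ``max_offset`` of each anchor
    is taken; a pair is emitted when both sides match. Each gene joins at most
    one pair — when several blocks compete for a gene the closest block wins.
    """
    required = {"block_id", "chrA", "startA", "endA", "chrB", "startB", "endB"}
    if not required <= set(blocks.columns):
        raise ValueError(f"malformed block records, need columns {sorted(required)}")
    by_id = {m.gene_id: m for m in gene_models}
    fam_models = [by_id[g] for g in family_genes if g in by_id]

    candidates: List[Tuple[int, str, str, str]] = []  # (worst offset, block, geneA, geneB)
    for row in blocks.itertuples(index=False):
        best = {}
        for side, chrom, s, e in (
            ("A", row.chrA, int(row.startA), int(row.endA)),
            ("B", row.chrB, int(row.startB), int(row.endB)),
        ):
            near = [
                (_span_offset(m.start, m.end, s, e), m.gene_id)
                for m in fam_models
                if m.chromosome == chrom
                and _span_offset(m.start, m.end, s, e) <= max_offset
            ]
            if near:
                best[side] = min(near)
        if "A" in best and "B" in best and best["A"][1] != best["B"][1]:
            worst = max(best["A"][0], best["B"][0])
            candidates.append((worst, str(row.block_id), best["A"][1], best["B"][1]))

    pairs: List[SegmentalPair] = []
    used: set = set()
    for worst, block_id, ga, gb in sorted(candidates):
        if ga in used or gb in used:
            continue
        used.update((ga, gb))
        pairs.append(SegmentalPair(ga, gb, block_id, worst))
    return pairs


# ---------------------------------------------------------------------------
# global alignment identity
# ---------------------------------------------------------------------------

def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent identity from a Needleman–Wunsch global alignment.

    identity = 100 · (matching columns) / (alignment columns).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def annotate_pair_identity(
    pairs: Sequence[SegmentalPair], proteins: Mapping[str, str],
    gene_to_protein: Mapping[str, str],
) -> None:
    """Fill identity_pct of each pair from representative protein sequences."""
    for p in pairs:
        a = proteins[gene_to_protein[p.gene_a]]
        b = proteins[gene_to_protein[p.gene_b]]
        p.identity_pct = global_identity(a, b)
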