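"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive or naive computation, staying
deliberately independent of the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import DIWV


# --- GH...WD repeat scan ----------------------------------------------------

def scan_repeats_bruteforce(seq: str, min_sep: int = 20, max_sep: int = 50):
    """Enumerate all GH/WD anchor pairs, then apply the same greedy rule."""
    seq = seq.upper()
    gh = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "GH"]
    wd = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "WD"]
    pairs = []
    for g in gh:
        for w in wd:
            sep = w - (g + 1) - 1
            if min_sep <= sep <= max_sep:
                pairs.append((g, w))
    spans = []
    cursor = -1
    for g in sorted(gh):
        if g <= cursor:
            continue
        cands = [w for (gg, w) in pairs if gg == g and w > cursor]
        if not cands:
            continue
        w = min(cands)
        spans.append((g + 1, w + 2))
        cursor = w + 1
    return spans


# --- tandem grouping --------------------------------------------------------

def tandem_groups_bruteforce(
    family: Set[str], layout: Dict[str, List[str]], max_intervening: int = 5
) -> List[Set[str]]:
    """All-pairs linkage plus union-find over the positional gene order.

    ``layout`` maps chromosome -> gene ids in positional order.
    """
    parent = {g: g for g in family}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for chrom, order in layout.items():
        pos = {g: i for i, g in enumerate(order)}
        fam_here = [g for g in order if g in family]
        for a, b in itertools.combinations(fam_here, 2):
            if abs(pos[a] - pos[b]) - 1 <= max_intervening:
                union(a, b)
    components: Dict[str, Set[str]] = {}
    for g in family:
        components.setdefault(find(g), set()).add(g)
    return [c for c in components.values() if len(c) > 1]


# --- complete-linkage clustering -------------------------------------------

def complete_linkage_partition(X: np.ndarray, n_groups: int) -> List[Set[int]]:
    """Naive O(n^3) agglomerative complete linkage on euclidean distances."""
    n = len(X)
    clusters: List[Set[int]] = [{i} for i in range(n)]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))

    def linkage_dist(a: Set[int], b: Set[int]) -> float:
        return max(d[i, j] for i in a for j in b)

    while len(clusters) > n_groups:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = linkage_dist(clusters[i], clusters[j])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


# --- global alignment -------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def global_alignment_score_bruteforce(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Best global alignment score by exhaustive recursion over alignments.

    A gap of length L costs gap_open + (L-1)*gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(_BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "m"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "a" else gap_open
            options.append(-cost + best(i + 1, j, "a"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "b" else gap_open
            options.append(-cost + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "m")


# --- statistics -------------------------------------------------------------

def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


def instability_index_naive(seq: str) -> float:
    total = 0.0
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if a == "X" or b == "X":
            continue
        total += DIWV[a][b]
    return 10.0 / len(seq) * total


def standard_error_naive(condition_means: Sequence[float]) -> float:
    """Two-pass sample sd of condition means divided by sqrt(#conditions)."""
    vals = list(map(float, condition_means))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return math.sqrt(var) / math.sqrt(n)


# --- promoter scan ----------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def scan_motif_naive(seq: str, pattern: str) -> List[Tuple[str, int]]:
    """Sliding-window IUPAC match on both strands; (strand, 1-based +pos)."""
    seq = seq.upper()
    pattern = pattern.upper()
    hits = []
    rc_seq = "".join(_RC[c] for c in reversed(seq))
    L = len(pattern)
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if all(wc != "N" and wc in _IUPAC[pc] for wc, pc in zip(window, pattern)):
            hits.append(("+", i + 1))
    for i in range(len(rc_seq) - L + 1):
        window = rc_seq[i : i + L]
        if all(wc != "N" and wc in _IUPAC[pc] for wc, pc in zip(window, pattern)):
            # map reverse-strand index back to a + strand start position
            hits.append(("-", len(seq) - (i + L) + 1))
    return sorted(hits)
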