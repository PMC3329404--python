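"""Permutation-calibrated Pearson co-expression network construction.

The edge threshold is not fixed a priori: pairwise correlations are computed
among a random sample of genes, the same computation is repeated after
independently permuting each gene's expression vector (destroying all
co-expression while preserving each gene's marginal distribution), and the
threshold is set where the null positive tail drops below a target exceedance
``alpha``. Seed genes whose expression barely varies across conditions
(standard error of condition means ≤ 500 signal units) are excluded first, so
constitutive expression cannot masquerade as co-expression. Candidate edges
are then confirmed by the t-test on r with n − 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class NullDistribution:
    values: np.ndarray
    n_genes_sampled: int
    n_pairs: int
    permutation_seed: int


@dataclass
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    pcc: float
    p_value: float
    n: int


@dataclass
class CoexpressionNetwork:
    nodes: Dict[str, str]               # node id -> class label
    edges: List[CoexpressionEdge]
    threshold_used: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, cls in self.nodes.items():
            g.add_node(node, node_class=cls)
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, pcc=e.pcc, p_value=e.p_value, n=e.n)
        return g


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (n ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must share one dimension")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r·√(n−2)/√(1−r²), df = n − 2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pairwise_upper(values: np.ndarray) -> np.ndarray:
    """Upper-triangle Pearson correlations between rows of ``values``."""
    r = np.corrcoef(values)
    iu = np.triu_indices_from(r, k=1)
    return r[iu]


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def permutation_threshold(
    matrix: pd.DataFrame,
    n_sample_genes: int = 1000,
    alpha: float = 0.001,
    seed: int = 0,
) -> Tuple[float, NullDistribution, np.ndarray]:
    """Calibrate the positive co-expression threshold against a permutation null.

    Steps: sample ``n_sample_genes`` rows without replacement; compute all
    pairwise correlations among them (the observed distribution); permute each
    sampled row independently and recompute all pairwise correlations (the
    null distribution); return the smallest r whose null exceedance fraction
    is ≤ ``alpha`` (positive tail), along with both distributions.
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 columns")
    rng = np.random.default_rng(seed)
    n_rows = values.shape[0]
    if n_rows < n_sample_genes:
        import warnings

        warnings.warn(
            f"matrix has {n_rows} rows < n_sample_genes={n_sample_genes}; using all rows"
        )
        sample = values
    else:
        idx = rng.choice(n_rows, size=n_sample_genes, replace=False)
        sample = values[idx]
    observed = _pairwise_upper(sample)
    permuted = sample.copy()
    for i in range(permuted.shape[0]):
        rng.shuffle(permuted[i])  # fresh independent permutation per gene
    null_values = _pairwise_upper(permuted)

    # smallest r with null exceedance <= alpha: with m = floor(alpha * n_pairs)
    # values allowed above it, that r is the (m+1)-th largest null value.
    n_pairs = len(null_values)
    m = int(math.floor(alpha * n_pairs))
    threshold = float(np.sort(null_values)[n_pairs - m - 1])
    null = NullDistribution(null_values, sample.shape[0], n_pairs, seed)
    return threshold, null, observed


def variability_filter(
    matrix: ExpressionMatrix,
    candidates: Sequence[str],
    se_threshold: float = 500.0,
) -> List[str]:
    """Keep candidate seed genes whose expression varies across conditions.

    SE = sd(per-condition mean raw signals) / sqrt(#conditions); a gene is
    retained only when SE > ``se_threshold`` (strict), discarding
    constitutively expressed seeds.
    """
    means = matrix.condition_means()
    if means.shape[1] < 2:
        raise ValueError("need at least 2 conditions to measure variability")
    retained = []
    for gene in candidates:
        vals = means.loc[gene].to_numpy(dtype=float)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        if se > se_threshold:
            retained.append(gene)
    return retained


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def build_network(
    matrix: pd.DataFrame,
    seed_genes: Sequence[str],
    threshold: float,
    alpha_p: float = 0.05,
    node_classes: Optional[Mapping[str, str]] = None,
    family_label: str = "family",
) -> CoexpressionNetwork:
    """Extract the co-expression network around a set of seed genes.

    Every seed gene is tested against every other gene in ``matrix`` (rows =
    genes, columns = samples, values on the scale correlations should be
    computed on). An edge is kept when pcc ≥ ``threshold`` and the r-test p is
    below ``alpha_p``. Seed–seed edges are allowed; each unordered pair is
    stored once. Node classes come from ``node_classes`` (seed genes default to
    ``family_label``, everything else to "other").
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    values = matrix.to_numpy(dtype=float)
    gene_ids = list(matrix.index)
    index_of = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in seed_genes if g not in index_of]
    if missing:
        raise ValueError(f"seed genes absent from matrix: {missing}")
    n = values.shape[1]
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    ok = norms > 0

    seen: Set[Tuple[str, str]] = set()
    edges: List[CoexpressionEdge] = []
    for seed in seed_genes:
        i = index_of[seed]
        if not ok[i]:
            continue
        r = centered @ centered[i] / (norms * norms[i])
        r[~ok] = 0.0
        for j in np.nonzero(r >= threshold)[0]:
            if j == i:
                continue
            a, b = gene_ids[i], gene_ids[j]
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            p = correlation_pvalue(float(min(1.0, max(-1.0, r[j]))), n)
            if p < alpha_p:
                seen.add(key)
                edges.append(CoexpressionEdge(key[0], key[1], float(r[j]), p, n))

    node_classes = node_classes or {}
    seeds = set(seed_genes)
    nodes: Dict[str, str] = {}
    for e in edges:
        for g in (e.gene_a, e.gene_b):
            if g not in nodes:
                if g in seeds:
                    nodes[g] = family_label
                else:
                    nodes[g] = node_classes.get(g, "other")
    return CoexpressionNetwork(nodes, edges, threshold)


def extract_class_subnetwork(
    network: CoexpressionNetwork,
    classes: Set[str],
    family_label: str = "family",
) -> CoexpressionNetwork:
    """Induced subnetwork on family nodes plus nodes of the given classes.

    An empty class selection yields the family-only subnetwork.
    """
    known = set(network.nodes.values())
    unknown = classes - known
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    keep_classes = set(classes) | {family_label}
    nodes = {g: c for g, c in network.nodes.items() if c in keep_classes}
    edges = [
        e for e in network.edges if e.gene_a in nodes and e.gene_b in nodes
    ]
    return CoexpressionNetwork(nodes, edges, network.threshold_used)
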