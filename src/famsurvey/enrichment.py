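"""Singular enrichment analysis: per-term Fisher's exact test with
Benjamini–Yekutieli FDR adjustment.

A gene list is tested against a flat background annotation (no ontology-graph
propagation): for each term, the one-sided hypergeometric tail probability of
seeing at least the observed number of annotated genes in the list, followed
by the Yekutieli step-up adjustment, which controls the FDR under arbitrary
dependence between terms at the price of a harmonic-number inflation factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int          # list genes carrying the term
    n: int          # list size
    K: int          # background genes carrying the term
    N: int          # background size
    p_value: float
    fdr: float
    significant: bool


def fisher_enrichment(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher p: P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_yekutieli(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjustment, returned in input order.

    adj_i = min_{j ≥ i} p_(j) · m · c(m) / j with c(m) = Σ 1/i, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def sea(
    gene_list: Sequence[str],
    annotation: pd.DataFrame,
    background: Sequence[str],
    fdr_cut: float = 0.05,
    min_term_size: int = 2,
) -> List[EnrichmentRow]:
    """Singular enrichment analysis of a gene list against a background.

    ``annotation`` has columns gene_id, term_id and optionally term_name.
    Terms mapping to fewer than ``min_term_size`` background genes are skipped.
    Rows are sorted by p-value.
    """
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        raise ValueError("empty gene list")
    bg: Set[str] = set(background)
    outside = [g for g in genes if g not in bg]
    if outside:
        raise ValueError(f"genes not in background: {outside}")

    ann = annotation[annotation["gene_id"].isin(bg)]
    names = {}
    if "term_name" in ann.columns:
        names = dict(zip(ann["term_id"], ann["term_name"]))
    term_genes: Dict[str, Set[str]] = {
        t: set(sub["gene_id"]) for t, sub in ann.groupby("term_id")
    }
    N = len(bg)
    n = len(genes)
    gene_set = set(genes)

    rows: List[EnrichmentRow] = []
    for term in sorted(term_genes):
        carriers = term_genes[term]
        K = len(carriers)
        if K < min_term_size:
            continue
        k = len(carriers & gene_set)
        p = fisher_enrichment(k, n, K, N)
        rows.append(
            EnrichmentRow(term, names.get(term, term), k, n, K, N, p, 1.0, False)
        )
    fdrs = adjust_yekutieli([r.p_value for r in rows])
    for row, fdr in zip(rows, fdrs):
        row.fdr = float(fdr)
        row.significant = row.fdr < fdr_cut
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=["term_id", "term_name", "k", "n", "K", "N", "p_value", "fdr", "significant"],
    )
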