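"""Expression profiling: probe collapse, presence filtering, clustering, DE.

The analysis conventions follow classic Affymetrix practice: signals are
summarized per probe set, a gene with several probe sets keeps the probe with
the higher mean signal, detection flags (P/M/A) gate which genes count as
expressed, profiles are log2-transformed before euclidean complete-linkage
clustering, and differential expression against a reference condition combines
a two-sample t-test on log2 replicate signals with a linear fold-change
criterion (up: FC > 2 and p < 0.05; down: FC < 0.5 and p < 0.05).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    gene_id: str
    condition: str
    fold_change: float      # linear ratio condition/reference of replicate means
    p_value: float
    direction: str          # up / down / ns


@dataclass
class ExpressionGroups:
    linkage_matrix: np.ndarray          # scipy linkage encoding of the dendrogram
    labels: Dict[str, int]              # gene -> group id (1..n_groups)
    gene_ids: List[str]
    metric: str = "euclidean"
    linkage: str = "complete"


# ---------------------------------------------------------------------------
# probe handling
# ---------------------------------------------------------------------------

def collapse_probes(
    matrix: ExpressionMatrix,
    probemap: pd.DataFrame,
    universe: Optional[Sequence[str]] = None,
) -> Tuple[ExpressionMatrix, List[str]]:
    """Collapse probe rows to gene rows.

    For a gene with several probes the probe with the higher mean signal across
    all samples supplies every sample value (one probe per gene, not a
    per-cell max). A probe mapped to k genes contributes its row to each of
    them. Returns the gene-level matrix and the list of genes without any
    usable probe (dropped); ``universe`` extends that check to genes absent
    from the probe map entirely (e.g. the full family catalog).
    """
    if probemap.empty:
        raise ValueError("empty probe map")
    probe_means = matrix.values.mean(axis=1)
    rows = {}
    flag_rows = {}
    mapped = set(probemap["gene_id"])
    dropped: List[str] = [g for g in (universe or []) if g not in mapped]
    for gene_id, sub in probemap.groupby("gene_id", sort=True):
        probes = [p for p in sub["probe_id"] if p in matrix.values.index]
        if not probes:
            dropped.append(gene_id)
            continue
        best = max(probes, key=lambda p: (probe_means[p], p))
        rows[gene_id] = matrix.values.loc[best]
        if matrix.flags is not None:
            flag_rows[gene_id] = matrix.flags.loc[best]
    values = pd.DataFrame(rows).T
    values.columns = matrix.values.columns
    flags = None
    if matrix.flags is not None:
        flags = pd.DataFrame(flag_rows).T
        flags.columns = matrix.flags.columns
        flags = flags.loc[values.index]
    return ExpressionMatrix(values, matrix.samples, flags), sorted(dropped)


def presence_filter(matrix: ExpressionMatrix) -> Tuple[List[str], List[str]]:
    """Split genes into expressed (≥1 Present flag) and never-present.

    Without a flags table every gene counts as expressed (logged fallback).
    """
    if matrix.flags is None:
        logger.warning("no detection flags supplied; treating every gene as expressed")
        return list(matrix.values.index), []
    present = (matrix.flags == "P").any(axis=1)
    expressed = list(matrix.values.index[present])
    never = list(matrix.values.index[~present])
    return expressed, never


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_profiles(matrix: ExpressionMatrix, n_groups: int) -> ExpressionGroups:
    """Cluster replicate-averaged log2 profiles into expression groups.

    Complete-linkage agglomeration on euclidean distances of log2 condition
    means, cut into ``n_groups`` flat groups.
    """
    means = matrix.condition_means()
    if len(means) < n_groups:
        raise ValueError(f"n_groups={n_groups} exceeds {len(means)} genes")
    log_values = np.log2(means.to_numpy())
    Z = hierarchy.linkage(log_values, method="complete", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    gene_ids = list(means.index)
    return ExpressionGroups(Z, dict(zip(gene_ids, map(int, flat))), gene_ids)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _call_direction(fc: float, p: float, fc_threshold: float, alpha: float) -> str:
    if p < alpha and fc > fc_threshold:
        return "up"
    if p < alpha and fc < 1.0 / fc_threshold:
        return "down"
    return "ns"


def differential_vs_reference(
    matrix: ExpressionMatrix,
    reference_condition: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    log_scale_test: bool = True,
    equal_var: bool = True,
) -> List[DifferentialResult]:
    """Differential expression of every condition against a reference.

    Per gene and non-reference condition: a two-sample t-test (Student's by
    default) on log2 replicate signals, and the linear fold change of replicate
    means on the raw scale. Thresholds are strict: FC exactly at the threshold
    is not a call.
    """
    if reference_condition not in matrix.conditions:
        raise ValueError(f"reference condition {reference_condition!r} not in matrix")
    ref_cols = matrix.columns_for(reference_condition)
    if len(ref_cols) < 2:
        raise ValueError("need at least two replicates per condition for the t-test")
    ref_raw = matrix.values[ref_cols].to_numpy()
    ref_test = np.log2(ref_raw) if log_scale_test else ref_raw
    results: List[DifferentialResult] = []
    for condition in matrix.conditions:
        if condition == reference_condition:
            continue
        cols = matrix.columns_for(condition)
        if len(cols) < 2:
            raise ValueError(f"condition {condition!r} has a single replicate")
        raw = matrix.values[cols].to_numpy()
        test = np.log2(raw) if log_scale_test else raw
        t, p = stats.ttest_ind(test, ref_test, axis=1, equal_var=equal_var)
        fc = raw.mean(axis=1) / ref_raw.mean(axis=1)
        p = np.nan_to_num(p, nan=1.0)  # zero-variance ties
        for gene, f_i, p_i in zip(matrix.values.index, fc, p):
            results.append(
                DifferentialResult(
                    gene, condition, float(f_i), float(p_i),
                    _call_direction(float(f_i), float(p_i), fc_threshold, alpha),
                )
            )
    return results


def hormone_response(
    matrix: ExpressionMatrix,
    control: str = "CK",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> Tuple[Dict[str, List[DifferentialResult]], Dict[int, List[str]]]:
    """Per-treatment differential calls against the untreated control.

    Returns results keyed by treatment plus an overlap summary mapping
    k ∈ {1, 2, 3, …} to the genes responsive to exactly k treatments.
    """
    if control not in matrix.conditions:
        raise ValueError(f"control condition {control!r} missing from hormone matrix")
    results = differential_vs_reference(matrix, control, fc_threshold, alpha)
    by_treatment: Dict[str, List[DifferentialResult]] = {}
    for r in results:
        by_treatment.setdefault(r.condition, []).append(r)
    responders: Dict[str, set] = {}
    for treatment, rows in by_treatment.items():
        responders[treatment] = {r.gene_id for r in rows if r.direction != "ns"}
    counts: Dict[str, int] = {}
    for genes in responders.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    overlap: Dict[int, List[str]] = {
        k: sorted(g for g, c in counts.items() if c == k)
        for k in range(1, len(by_treatment) + 1)
    }
    return by_treatment, overlap


def differential_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "condition": r.condition,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "regulation": r.direction,
            }
            for r in results
        ],
        columns=["gene_id", "condition", "fold_change", "p_value", "regulation"],
    )
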