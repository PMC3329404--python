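"""End-to-end orchestration: catalog → duplication → expression → hormone →
promoter → co-expression → enrichment, with per-stage TSV artifacts and a
plain-text run manifest. Re-running with the same configuration is
bit-identical."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import coexpression, duplication, enrichment, expression, io, promoter
from .catalog import build_catalog, catalog_table
from .config import SimConfig

logger = logging.getLogger(__name__)

STAGES = [
    "catalog",
    "duplication",
    "expression",
    "hormone",
    "promoter",
    "coexpress",
    "enrich",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths, stage toggles and analysis parameters."""

    # inputs
    gene_models: str = "gene_models.gff3"
    proteins: str = "proteins.fasta"
    domains: str = "domains.tsv"
    expression: str = "expression.tsv"
    expression_meta: str = "expression_samples.tsv"
    expression_flags: str = "expression_flags.tsv"
    hormone: str = "hormone.tsv"
    hormone_meta: str = "hormone_samples.tsv"
    hormone_flags: str = "hormone_flags.tsv"
    probemap: str = "probemap.tsv"
    blocks: str = "blocks.tsv"
    promoters: str = "promoters.fasta"
    motifs: str = "motifs.tsv"
    annotation: str = "annotation.tsv"
    node_classes: str = ""           # optional gene_id/class TSV
    # stage toggles
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    # parameters (family survey defaults)
    max_intervening: int = 5
    max_offset: int = 500_000
    fc_threshold: float = 2.0
    alpha: float = 0.05
    n_sample_genes: int = 1000
    permutation_alpha: float = 0.001
    se_threshold: float = 500.0
    fdr_cut: float = 0.05
    n_groups: int = 2
    reference_condition: str = "seed"
    hormone_control: str = "CK"
    min_component_size: int = 5
    seed: int = 0

    def resolve(self, base: Path) -> "PipelineConfig":
        out = PipelineConfig(**{**asdict(self)})
        for name in (
            "gene_models", "proteins", "domains", "expression", "expression_meta",
            "expression_flags", "hormone", "hormone_meta", "hormone_flags",
            "probemap", "blocks", "promoters", "motifs", "annotation", "node_classes",
        ):
            value = getattr(out, name)
            if value:
                setattr(out, name, str(Path(base) / value))
        return out


_STAGE_INPUTS = {
    "catalog": ["gene_models", "proteins", "domains"],
    "duplication": ["gene_models", "proteins", "domains", "blocks"],
    "expression": ["expression", "expression_meta", "probemap",
                   "gene_models", "proteins", "domains"],
    "hormone": ["hormone", "hormone_meta", "probemap"],
    "promoter": ["promoters", "motifs"],
    "coexpress": ["expression", "expression_meta", "probemap"],
    "enrich": ["annotation"],
}


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the enabled stages and write artifacts plus a manifest to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # validation-first: every enabled stage's inputs must exist before work starts
    for stage in config.stages:
        if stage not in STAGES:
            raise PipelineError(stage, "unknown stage")
        for attr in _STAGE_INPUTS[stage]:
            path = getattr(config, attr)
            if path and not Path(path).exists():
                raise PipelineError(stage, f"missing input file {path} ({attr})")

    manifest: Dict[str, object] = {
        "parameters": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    state: Dict[str, object] = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            rows = _STAGE_FUNCS[stage](config, outdir, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - surface stage name and cause
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {"rows": rows}
        logger.info("stage %s complete (%s rows)", stage, rows)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_catalog_inputs(config: PipelineConfig, state: Dict[str, object]):
    if "members" in state:
        return
    models = io.read_gene_models(config.gene_models)
    proteins = {r.id: str(r.seq) for r in io.read_fasta(config.proteins)}
    hits = io.read_domain_table(config.domains)
    state["gene_models"] = models
    state["proteins"] = proteins
    state["members"] = build_catalog(models, proteins, hits)


def _stage_catalog(config: PipelineConfig, outdir: Path, state) -> int:
    _load_catalog_inputs(config, state)
    table = catalog_table(state["members"])
    table.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    return len(table)


def _stage_duplication(config: PipelineConfig, outdir: Path, state) -> int:
    _load_catalog_inputs(config, state)
    members = state["members"]
    models = state["gene_models"]
    fam_ids = [m.gene_id for m in members]
    groups = duplication.find_tandem_groups(fam_ids, models, config.max_intervening)
    pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "members": ",".join(g.members),
                "intervening": ",".join(map(str, g.intervening)),
                "gaps_bp": ",".join(map(str, g.gaps_bp)),
            }
            for g in groups
        ],
        columns=["group_id", "members", "intervening", "gaps_bp"],
    ).to_csv(outdir / "tandem_groups.tsv", sep="\t", index=False)

    blocks = io.read_blocks(config.blocks)
    pairs = duplication.assign_segmental_pairs(fam_ids, models, blocks, config.max_offset)
    gene_to_protein = {m.gene_id: m.representative_protein_id for m in members}
    duplication.annotate_pair_identity(pairs, state["proteins"], gene_to_protein)
    pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "block_id": p.block_id,
                "offset_bp": p.offset_bp,
                "identity_pct": round(p.identity_pct, 2),
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "block_id", "offset_bp", "identity_pct"],
    ).to_csv(outdir / "segmental_pairs.tsv", sep="\t", index=False)
    state["tandem_groups"] = groups
    state["segmental_pairs"] = pairs
    return len(groups) + len(pairs)


def _load_expression(config: PipelineConfig, state) -> None:
    if "gene_matrix" in state:
        return
    _load_catalog_inputs(config, state)
    flags = config.expression_flags if config.expression_flags and Path(config.expression_flags).exists() else None
    matrix = io.read_expression(config.expression, config.expression_meta, flags)
    probemap = io.read_probe_map(config.probemap)
    universe = [m.gene_id for m in state["members"]]
    gene_matrix, dropped = expression.collapse_probes(matrix, probemap, universe)
    expressed, never = expression.presence_filter(gene_matrix)
    state["gene_matrix"] = gene_matrix
    state["dropped_genes"] = dropped
    state["expressed"] = expressed
    state["never_present"] = never


def _stage_expression(config: PipelineConfig, outdir: Path, state) -> int:
    _load_expression(config, state)
    gene_matrix = state["gene_matrix"]
    expressed = state["expressed"]
    sub = gene_matrix.subset_rows(expressed)
    groups = expression.cluster_profiles(sub, config.n_groups)
    pd.DataFrame(
        sorted(groups.labels.items()), columns=["gene_id", "group"]
    ).to_csv(outdir / "expression_groups.tsv", sep="\t", index=False)
    de = expression.differential_vs_reference(
        sub, config.reference_condition, config.fc_threshold, config.alpha
    )
    table = expression.differential_table(de)
    table.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": state["never_present"]}
    ).to_csv(outdir / "never_present.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": state["dropped_genes"]}).to_csv(
        outdir / "genes_without_probes.tsv", sep="\t", index=False
    )
    state["de"] = de
    return len(table)


def _stage_hormone(config: PipelineConfig, outdir: Path, state) -> int:
    flags = config.hormone_flags if config.hormone_flags and Path(config.hormone_flags).exists() else None
    matrix = io.read_expression(config.hormone, config.hormone_meta, flags)
    probemap = io.read_probe_map(config.probemap)
    gene_matrix, _ = expression.collapse_probes(matrix, probemap)
    by_treatment, overlap = expression.hormone_response(
        gene_matrix, config.hormone_control, config.fc_threshold, config.alpha
    )
    rows = [r for results in by_treatment.values() for r in results]
    expression.differential_table(rows).to_csv(
        outdir / "hormone_response.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"n_treatments": k, "genes": ",".join(v)} for k, v in sorted(overlap.items())],
        columns=["n_treatments", "genes"],
    ).to_csv(outdir / "hormone_overlap.tsv", sep="\t", index=False)
    state["hormone_overlap"] = overlap
    responsive = sorted({g for v in overlap.values() for g in v})
    state["hormone_responsive"] = responsive
    return len(rows)


def _stage_promoter(config: PipelineConfig, outdir: Path, state) -> int:
    promoters = {r.id: str(r.seq) for r in io.read_fasta(config.promoters, mode="dna")}
    library = io.read_motif_library(config.motifs)
    scope = state.get("hormone_responsive") or sorted(promoters)
    scope = [g for g in scope if g in promoters]
    hits = promoter.scan_promoters({g: promoters[g] for g in scope}, library)
    pd.DataFrame(
        [
            {
                "promoter_id": h.promoter_id,
                "motif_name": h.motif_name,
                "strand": h.strand,
                "position": h.position,
                "matched_sequence": h.matched_sequence,
            }
            for h in hits
        ],
        columns=["promoter_id", "motif_name", "strand", "position", "matched_sequence"],
    ).to_csv(outdir / "promoter_hits.tsv", sep="\t", index=False)
    table = promoter.element_presence_table(scope, hits, library)
    table.to_csv(outdir / "element_presence.tsv", sep="\t")
    return len(hits)


def _stage_coexpress(config: PipelineConfig, outdir: Path, state) -> int:
    _load_catalog_inputs(config, state)
    _load_expression(config, state)
    gene_matrix = state["gene_matrix"]
    expressed = set(state["expressed"])
    log_means = np.log2(gene_matrix.condition_means())
    log_means = log_means.loc[[g for g in log_means.index if g in expressed]]

    threshold, null, observed = coexpression.permutation_threshold(
        log_means, config.n_sample_genes, config.permutation_alpha, config.seed
    )
    pd.DataFrame({"null_pcc": null.values}).to_csv(
        outdir / "null_distribution.tsv", sep="\t", index=False
    )
    members = [m.gene_id for m in state["members"]]
    candidates = [g for g in members if g in log_means.index]
    seeds = coexpression.variability_filter(
        gene_matrix.subset_rows(list(log_means.index)), candidates, config.se_threshold
    )
    node_classes = {}
    if config.node_classes and Path(config.node_classes).exists():
        df = pd.read_csv(config.node_classes, sep="\t", dtype=str)
        node_classes = dict(zip(df["gene_id"], df["class"]))
    network = coexpression.build_network(
        log_means, seeds, threshold, config.alpha, node_classes
    )
    io.write_network(network.edges, outdir / "network_edges.tsv")
    pd.DataFrame(
        sorted(network.nodes.items()), columns=["gene_id", "class"]
    ).to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    with open(outdir / "network_summary.json", "w") as fh:
        json.dump(
            {
                "threshold": threshold,
                "n_seeds": len(seeds),
                "n_nodes": len(network.nodes),
                "n_edges": len(network.edges),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    state["network"] = network
    state["threshold"] = threshold
    return len(network.edges)


def _stage_enrich(config: PipelineConfig, outdir: Path, state) -> int:
    annotation = io.read_annotation(config.annotation)
    background = sorted(set(annotation["gene_id"]))
    network = state.get("network")
    rows_out = []
    if network is not None and network.edges:
        g = network.to_networkx()
        import networkx as nx

        components = [
            sorted(c) for c in nx.connected_components(g)
            if len(c) >= config.min_component_size
        ]
    else:
        components = []
    for i, comp in enumerate(sorted(components), 1):
        testable = [g_ for g_ in comp if g_ in set(background)]
        if not testable:
            continue
        rows = enrichment.sea(testable, annotation, background, config.fdr_cut)
        for r in rows:
            rows_out.append(
                {
                    "component": i,
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
            )
    pd.DataFrame(
        rows_out,
        columns=["component", "term_id", "term_name", "k", "n", "K", "N",
                 "p_value", "fdr", "significant"],
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return len(rows_out)


_STAGE_FUNCS = {
    "catalog": _stage_catalog,
    "duplication": _stage_duplication,
    "expression": _stage_expression,
    "hormone": _stage_hormone,
    "promoter": _stage_promoter,
    "coexpress": _stage_coexpress,
    "enrich": _stage_enrich,
}


# ---------------------------------------------------------------------------
# synthetic demo materialization
# ---------------------------------------------------------------------------

def write_synthetic_inputs(dataset, directory) -> PipelineConfig:
    """Write a synthetic dataset as pipeline input files; returns the config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=dataset.config.seed).resolve(directory)
    io.write_gene_models(dataset.gene_models, cfg.gene_models)
    io.write_fasta(sorted(dataset.proteins.items()), cfg.proteins)
    io.write_domain_table(dataset.domain_hits, cfg.domains)
    io.write_expression(
        dataset.developmental, cfg.expression, cfg.expression_meta, cfg.expression_flags
    )
    io.write_expression(dataset.hormone, cfg.hormone, cfg.hormone_meta, cfg.hormone_flags)
    dataset.probemap.to_csv(cfg.probemap, sep="\t", index=False)
    dataset.truth.blocks.to_csv(cfg.blocks, sep="\t", index=False)
    io.write_fasta(sorted(dataset.promoters.items()), cfg.promoters)
    dataset.motif_library.to_csv(cfg.motifs, sep="\t", index=False)
    dataset.terms.to_csv(cfg.annotation, sep="\t", index=False)
    classes = dataset.node_classes
    node_path = directory / "node_classes.tsv"
    pd.DataFrame(
        sorted(classes.items()), columns=["gene_id", "class"]
    ).to_csv(node_path, sep="\t", index=False)
    cfg.node_classes = str(node_path)
    cfg.reference_condition = dataset.truth.reference_condition
    return cfg
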