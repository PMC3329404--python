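"""Synthetic survey substrate with known ground truth.

Generates an internally consistent genome (gene models on chromosomes, family
proteins with planted GH…WD repeats and subfamily-diagnostic domains, tandem
clusters, segmental duplication blocks), a developmental expression matrix
with planted co-expression modules and differentially expressed genes, a
pooled-time-point phytohormone experiment, promoters with planted cis
elements, and a flat term annotation with planted enrichment — everything a
downstream stage consumes, with the planted truth recorded for testing.

Random protein segments are drawn from an 18-letter alphabet without H or D so
that GH/WD dipeptides occur exactly where planted; this is a deliberate
simplification (no realistic residue composition is attempted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .io import DomainHit, ExpressionMatrix, GeneModel

AA18 = "ACEFGIKLMNPQRSTVWY"  # no H, no D: GH/WD appear only where planted
DNA = "ACGT"

#: canonical subfamily plan for a 200-gene family; scaled to the configured size
_SUBFAMILY_BASE = {
    "B": 7, "C": 5, "D": 4, "E": 4, "F": 3,
    "G": 4, "H": 3, "I": 2, "J": 2, "K": 21,
}
_DIAGNOSTIC_DOMAIN = {
    "B": ["LisH"],
    "C": ["Utp12", "Utp13", "Utp15", "Utp21"],
    "D": ["WDAD", "COPI-alpha-C"],
    "E": ["RBBP4", "CAF1-C"],
    "F": ["NLE"],
    "G": ["Pkinase", "HEAT"],
    "H": ["BEACH"],
    "I": ["zf-C3HC4"],
    "J": ["BCAS3"],
    "K": ["F-box", "U-box", "DUF1899"],
}

#: demo cis-element library (PLACE-style degenerate patterns)
MOTIF_LIBRARY_ROWS = [
    ("ASF1MOTIF", "TGACG", "auxin"),
    ("AUXRE", "TGTCTC", "auxin"),
    ("NTBBF1", "ACTTTA", "auxin"),
    ("GARE", "TAACAAR", "gibberellin"),
    ("PYRIMIDINEBOX", "CCTTTT", "gibberellin"),
    ("GAMYB", "CAACTC", "gibberellin"),
    ("ARR1AT", "NGATT", "cytokinin"),
    ("CPBCSPOR", "TATTAG", "cytokinin"),
    ("ABRE", "ACGTGGC", "abscisic"),
    ("CAATBOX", "CCAAT", "general"),
]
_HORMONE_CLASS = {"NAA": "auxin", "GA3": "gibberellin", "KT": "cytokinin"}

_NODE_CLASSES = ["MYB", "bHLH", "MADS-box", "histone"]


class SizingError(ConfigError):
    """The requested family does not fit into the genome."""


@dataclass
class GroundTruth:
    """Planted structure underlying a synthetic dataset."""

    family_gene_ids: Set[str] = field(default_factory=set)
    subfamily_of: Dict[str, str] = field(default_factory=dict)
    tandem_groups: List[List[str]] = field(default_factory=list)
    segmental_pairs: List[Tuple[str, str]] = field(default_factory=list)
    segmental_identity: Dict[Tuple[str, str], float] = field(default_factory=dict)
    module_of: Dict[str, int] = field(default_factory=dict)
    de_genes: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    hormone_responders: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    planted_motifs: Dict[str, List[Tuple[str, str, int]]] = field(default_factory=dict)
    enriched_terms: Dict[int, List[str]] = field(default_factory=dict)
    # artifact plumbing
    all_gene_ids: List[str] = field(default_factory=list)
    gene_to_representative: Dict[str, str] = field(default_factory=dict)
    absent_genes: Set[str] = field(default_factory=set)
    no_probe_genes: Set[str] = field(default_factory=set)
    shared_probe_pairs: List[Tuple[str, str]] = field(default_factory=list)
    node_class_of: Dict[str, str] = field(default_factory=dict)
    reference_condition: str = "seed"
    blocks: Optional[pd.DataFrame] = None
    repeat_spans: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA18), size=length))


def _family_protein(rng: np.random.Generator) -> Tuple[str, List[Tuple[int, int]]]:
    """A protein with 4–7 planted GH…WD repeats; returns (sequence, spans)."""
    n_rep = int(rng.integers(4, 8))
    pieces = [_random_peptide(rng, int(rng.integers(30, 61)))]
    pos = len(pieces[0])
    spans = []
    for k in range(n_rep):
        sep = int(rng.integers(20, 51))
        unit = "GH" + _random_peptide(rng, sep) + "WD"
        spans.append((pos + 1, pos + len(unit)))
        pieces.append(unit)
        pos += len(unit)
        linker = _random_peptide(rng, int(rng.integers(3, 10)))
        pieces.append(linker)
        pos += len(linker)
    pieces.append(_random_peptide(rng, int(rng.integers(20, 51))))
    return "".join(pieces), spans


def _subfamily_plan(rng: np.random.Generator, n_family: int) -> List[str]:
    scale = n_family / 200.0
    labels: List[str] = []
    for sub, base in _SUBFAMILY_BASE.items():
        count = max(1, int(round(base * scale))) if n_family >= 22 else (1 if base >= 5 else 0)
        labels.extend([sub] * count)
    if len(labels) >= n_family:
        labels = labels[: max(0, n_family - 1)]
    labels.extend(["A"] * (n_family - len(labels)))
    rng.shuffle(labels)
    return labels


def generate_genome(
    config: SimConfig,
) -> Tuple[List[GeneModel], Dict[str, str], List[DomainHit], GroundTruth]:
    """Generate gene models, protein sequences, the domain table and truth."""
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    truth = GroundTruth()

    n_chrom = config.n_chromosomes
    per_chrom = config.genes_per_chromosome

    # --- tandem/single item plan -------------------------------------------
    sizes: List[int] = []
    if config.n_tandem_groups > 0:
        sizes = [3] + [2] * (config.n_tandem_groups - 1)
    n_tandem_genes = sum(sizes)
    if n_tandem_genes > config.n_family_genes:
        raise SizingError("tandem groups require more family genes than configured")
    items: List[dict] = [{"kind": "tandem", "size": s} for s in sizes]
    items += [{"kind": "single"} for _ in range(config.n_family_genes - n_tandem_genes)]
    order = rng.permutation(len(items))
    chrom_items: List[List[dict]] = [[] for _ in range(n_chrom)]
    for rank, idx in enumerate(order):
        chrom_items[rank % n_chrom].append(items[idx])

    # --- layout per chromosome ---------------------------------------------
    chrom_names = [f"chr{c + 1:02d}" for c in range(n_chrom)]
    slots_per_chrom: List[List[dict]] = []
    for c, its in enumerate(chrom_items):
        slots: List[dict] = []
        fam_genes = sum(it.get("size", 1) for it in its)
        intra = []
        for it in its:
            if it["kind"] == "tandem":
                it["intervening"] = [int(rng.choice([0, 0, 1, 2])) for _ in range(it["size"] - 1)]
                intra.append(sum(it["intervening"]))
            else:
                intra.append(0)
        fillers = per_chrom - fam_genes - sum(intra)
        n_gaps = len(its) + 1
        if fillers < 6 * max(0, len(its) - 1):
            raise SizingError(
                f"{chrom_names[c]}: {per_chrom} slots cannot hold {fam_genes} family "
                f"genes with 6-gene spacing"
            )
        gap_fill = [0] + [6] * (len(its) - 1) + [0] if its else [fillers]
        extra = fillers - sum(gap_fill)
        if its and extra > 0:
            add = rng.multinomial(extra, np.ones(n_gaps) / n_gaps)
            gap_fill = [g + int(a) for g, a in zip(gap_fill, add)]
        for i, it in enumerate(its):
            slots.extend({"kind": "bg"} for _ in range(gap_fill[i]))
            if it["kind"] == "single":
                slots.append({"kind": "fam"})
            else:
                slots.append({"kind": "fam", "tandem": id(it), "gap": "first"})
                for r in it["intervening"]:
                    for _ in range(r):
                        slots.append({"kind": "bg", "small": True})
                    slots.append({"kind": "fam", "tandem": id(it)})
        if its:
            slots.extend({"kind": "bg"} for _ in range(gap_fill[-1]))
        else:
            slots.extend({"kind": "bg"} for _ in range(fillers))
        slots_per_chrom.append(slots)

    # --- subfamilies, proteins, coordinates --------------------------------
    n_family = config.n_family_genes
    subfamilies = _subfamily_plan(rng, n_family)
    models: List[GeneModel] = []
    proteins: Dict[str, str] = {}
    domain_hits: List[DomainHit] = []
    tandem_members: Dict[int, List[str]] = {}
    fam_counter = 0
    gene_counter = 0
    lo_gap, hi_gap = config.tandem_gap_bp

    for chrom, slots in zip(chrom_names, slots_per_chrom):
        pos = int(rng.integers(5_000, 20_000))
        prev_tandem = None
        for slot in slots:
            gene_counter += 1
            gid = f"G{gene_counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            in_tandem = slot.get("tandem")
            # gap preceding this gene; adjacent tandem members take a gap in
            # the configured tandem range, intervener-separated members stay
            # inside it through short intervener gaps
            if in_tandem is not None and prev_tandem == in_tandem:
                gap = int(rng.integers(lo_gap, hi_gap + 1))
            elif slot.get("small"):
                gap = int(rng.integers(1_000, 1_501))
            else:
                gap = int(rng.integers(2_000, 20_001))
            start = pos + gap
            if slot["kind"] == "fam":
                fam_counter += 1
                sub = subfamilies[fam_counter - 1]
                seq, spans = _family_protein(rng)
                tid = f"{gid}.1"
                transcripts = [(tid, len(seq))]
                proteins[tid] = seq
                if rng.random() < 0.25:
                    short = max(60, int(len(seq) * 0.7))
                    tid2 = f"{gid}.2"
                    transcripts.append((tid2, short))
                    proteins[tid2] = seq[:short]
                source = "smart" if rng.random() < 0.8 else "pfam"
                for s, e in spans:
                    domain_hits.append(DomainHit(tid, "WD40", s, e, source))
                if sub != "A":
                    choices = _DIAGNOSTIC_DOMAIN[sub]
                    dom = choices[(fam_counter - 1) % len(choices)]
                    domain_hits.append(DomainHit(tid, dom, 1, 25, source))
                end = start + 3 * len(seq) - 1
                model = GeneModel(gid, chrom, start, end, strand, transcripts)
                truth.family_gene_ids.add(gid)
                truth.subfamily_of[gid] = sub
                truth.gene_to_representative[gid] = tid
                truth.repeat_spans[tid] = spans
                if in_tandem is not None:
                    tandem_members.setdefault(in_tandem, []).append(gid)
            else:
                length = int(rng.integers(1_000, 2_001)) if slot.get("small") else int(
                    rng.integers(1_000, 4_001)
                )
                end = start + length - 1
                aa_len = int(rng.integers(150, 501))
                tid = f"{gid}.1"
                proteins[tid] = _random_peptide(rng, aa_len)
                model = GeneModel(gid, chrom, start, end, strand, [(tid, aa_len)])
                truth.gene_to_representative[gid] = tid
            models.append(model)
            truth.all_gene_ids.append(gid)
            pos = end
            prev_tandem = in_tandem

    truth.tandem_groups = [sorted(v, key=lambda g: int(g[1:])) for v in tandem_members.values()]
    truth.tandem_groups.sort(key=lambda grp: int(grp[0][1:]))

    # --- segmental pairs and blocks ----------------------------------------
    by_id = {m.gene_id: m for m in models}
    singles_by_chrom: Dict[str, List[str]] = {}
    in_tandem_ids = {g for grp in truth.tandem_groups for g in grp}
    for gid in sorted(truth.family_gene_ids - in_tandem_ids, key=lambda g: int(g[1:])):
        singles_by_chrom.setdefault(by_id[gid].chromosome, []).append(gid)
    eligible_chroms = [c for c in chrom_names if singles_by_chrom.get(c)]
    if config.n_segmental_pairs * 2 > sum(len(v) for v in singles_by_chrom.values()):
        raise SizingError("not enough single family genes for segmental pairs")
    block_rows = []
    used: Set[str] = set()
    for p in range(config.n_segmental_pairs):
        pool = [c for c in eligible_chroms if any(g not in used for g in singles_by_chrom[c])]
        if len(pool) < 2:
            raise SizingError("not enough chromosomes with free family genes for segmental pairs")
        ca, cb = (str(c) for c in rng.choice(pool, size=2, replace=False))
        ga = next(g for g in singles_by_chrom[ca] if g not in used)
        gb = next(g for g in singles_by_chrom[cb] if g not in used)
        used.update((ga, gb))
        target = float(rng.uniform(0.75, 0.95))
        # partner protein: substitution-mutated copy of the source protein
        src_tid = truth.gene_to_representative[ga]
        dst_tid = truth.gene_to_representative[gb]
        src_seq = proteins[src_tid]
        protected = set()
        for s, e in truth.repeat_spans[src_tid]:
            protected.update({s - 1, s, e - 2, e - 1})  # GH and WD anchors (0-based)
        seq = list(src_seq)
        mutable = [i for i in range(len(seq)) if i not in protected]
        n_mut = int(round((1.0 - target) * len(seq)))
        for i in rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False):
            alternatives = [a for a in AA18 if a != seq[i]]
            seq[i] = alternatives[int(rng.integers(len(alternatives)))]
        new_seq = "".join(seq)
        # swap in the mutated protein and refresh the partner's annotations;
        # secondary transcripts of the partner are dropped (their proteins
        # derived from the replaced sequence)
        mb = by_id[gb]
        for t, _ in mb.transcripts:
            proteins.pop(t, None)
        proteins[dst_tid] = new_seq
        mb.transcripts = [(dst_tid, len(new_seq))]
        domain_hits = [h for h in domain_hits if h.protein_id != dst_tid]
        for s, e in truth.repeat_spans[src_tid]:
            domain_hits.append(DomainHit(dst_tid, "WD40", s, e, "smart"))
        truth.repeat_spans[dst_tid] = list(truth.repeat_spans[src_tid])
        # both partners carry only WD40 (subfamily A), mirroring the bias of
        # segmental duplicates toward the domain-poor subfamily
        domain_hits = [
            h
            for h in domain_hits
            if not (h.protein_id in {src_tid, dst_tid} and h.domain_name != "WD40")
        ]
        truth.subfamily_of[ga] = truth.subfamily_of[gb] = "A"
        ma = by_id[ga]
        block_rows.append(
            {
                "block_id": f"B{p + 1:03d}",
                "chrA": ma.chromosome,
                "startA": max(1, ma.start - 2_000),
                "endA": ma.end + 2_000,
                "chrB": mb.chromosome,
                "startB": max(1, mb.start - 2_000),
                "endB": mb.end + 2_000,
            }
        )
        truth.segmental_pairs.append((ga, gb))
        truth.segmental_identity[(ga, gb)] = target
    truth.blocks = pd.DataFrame(
        block_rows,
        columns=["block_id", "chrA", "startA", "endA", "chrB", "startB", "endB"],
    )
    return models, proteins, domain_hits, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _stage_labels(n_tissues: int) -> List[str]:
    return ["seed"] + [f"stage{i:02d}" for i in range(2, n_tissues + 1)]


def _hormone_plan(treatments: Sequence[str]) -> List[Tuple[Tuple[str, ...], str]]:
    t = list(treatments)
    plan: List[Tuple[Tuple[str, ...], str]] = []

    def combo(idx: Tuple[int, ...], direction: str, count: int):
        names = tuple(t[i] for i in idx if i < len(t))
        if names:
            plan.extend([(names, direction)] * count)

    combo((0, 1, 2), "up", 3)
    combo((0, 1, 2), "down", 1)
    combo((0, 1), "up", 3)
    combo((0, 2), "up", 2)
    combo((2, 1), "up", 6)
    combo((1,), "up", 5)
    combo((2,), "up", 4)
    combo((2,), "down", 1)
    return plan


def generate_expression(
    config: SimConfig, truth: GroundTruth
) -> Tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Developmental and hormone expression matrices plus the probe map."""
    config.validate()
    if not truth.all_gene_ids:
        raise ConfigError("truth carries no gene ids; generate the genome first")
    if not truth.family_gene_ids <= set(truth.all_gene_ids):
        raise ConfigError("truth family ids not a subset of generated genes")
    rng = np.random.default_rng([2, config.seed])

    genes = list(truth.all_gene_ids)
    fam = sorted(truth.family_gene_ids, key=lambda g: int(g[1:]))
    background = [g for g in genes if g not in truth.family_gene_ids]
    n_family = len(fam)

    fam_pool = [str(g) for g in rng.permutation(fam)]

    def take(k: int) -> List[str]:
        if len(fam_pool) < k:
            raise SizingError("family too small for the planted expression structure")
        out = [fam_pool.pop() for _ in range(k)]
        return out

    absent = take(min(2, max(1, n_family // 100)))
    n_noprobe = max(1, int(round(0.08 * n_family)))
    no_probe = take(n_noprobe)
    shared_pairs = [tuple(take(2)) for _ in range(2 if n_family >= 40 else 1)]
    module_fam = {m: take(3) for m in range(1, config.n_modules + 1)}
    n_de = max(1, int(round(config.de_fraction * n_family)))
    de_genes = take(min(n_de, len(fam_pool) - 1))
    plan = _hormone_plan(config.hormone_treatments)
    plan = plan[: min(len(plan), max(3, len(fam_pool) // 2))]
    hormone_genes = take(len(plan))
    two_probe = [g for g in fam_pool[: max(1, int(round(0.18 * n_family)))]]

    truth.absent_genes = set(absent)
    truth.no_probe_genes = set(no_probe)
    truth.shared_probe_pairs = [tuple(p) for p in shared_pairs]

    # module assignment: planted family seeds plus background members
    bg_pool = [str(g) for g in rng.permutation(background)]
    for m in range(1, config.n_modules + 1):
        members = list(module_fam[m])
        need = config.module_size - len(members)
        if need > len(bg_pool):
            raise SizingError("not enough background genes for module members")
        members += [bg_pool.pop() for _ in range(need)]
        for g in members:
            truth.module_of[g] = m
        cls = _NODE_CLASSES[(m - 1) % len(_NODE_CLASSES)]
        for g in members:
            if g not in truth.family_gene_ids:
                truth.node_class_of[g] = cls

    # DE truth
    stages = _stage_labels(config.n_tissues)
    truth.reference_condition = stages[0]
    de_stage = {}
    for g in de_genes:
        stage = stages[1 + int(rng.integers(len(stages) - 1))]
        direction = "up" if rng.random() < 0.7 else "down"
        de_stage[g] = (stage, direction)
        truth.de_genes.setdefault(stage, set()).add((g, direction))

    # hormone truth
    for g, (names, direction) in zip(hormone_genes, plan):
        for t in names:
            truth.hormone_responders.setdefault(t, set()).add((g, direction))
    for t in config.hormone_treatments:
        truth.hormone_responders.setdefault(t, set())

    # --- baselines ----------------------------------------------------------
    flat_special = set(absent) | set(de_genes) | set(hormone_genes)
    baseline = {}
    for g in genes:
        if g in absent:
            baseline[g] = 30.0
        elif g in truth.module_of:
            baseline[g] = float(
                np.exp(rng.normal(config.module_baseline_log_mean, config.module_baseline_log_sd))
            )
        elif g in flat_special:
            baseline[g] = float(np.exp(rng.normal(7.3, 0.3)))
        else:
            baseline[g] = float(
                np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
            )

    n_t = config.n_tissues
    module_profiles = {
        m: rng.normal(0.0, config.module_profile_sd, size=n_t)
        for m in range(1, config.n_modules + 1)
    }

    gene_index = {g: i for i, g in enumerate(genes)}
    true_mean = np.empty((len(genes), n_t))
    for g in genes:
        i = gene_index[g]
        b = baseline[g]
        if g in truth.module_of:
            lat = module_profiles[truth.module_of[g]]
            eps = rng.normal(0.0, config.module_noise_sd, size=n_t)
            true_mean[i] = b * np.exp(lat + eps)
        elif g in flat_special:
            row = np.full(n_t, b)
            if g in de_stage:
                stage, direction = de_stage[g]
                j = stages.index(stage)
                row[j] = b * (config.de_fold if direction == "up" else 1.0 / config.de_fold)
            true_mean[i] = row
        else:
            true_mean[i] = b * np.exp(rng.normal(0.0, config.tissue_effect_sd, size=n_t))

    # --- probe map ----------------------------------------------------------
    shared_partner = {}
    for a, b in shared_pairs:
        shared_partner[b] = a  # b reuses a's probe (and hence a's signal)
    probe_rows = []
    probes_of: Dict[str, List[Tuple[str, float]]] = {}
    counter = 0

    def new_probe() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:05d}_at"

    for g in genes:
        if g in truth.no_probe_genes:
            continue
        if g in shared_partner:
            continue  # handled with its partner
        p1 = new_probe()
        probes_of[g] = [(p1, 1.0)]
        probe_rows.append({"probe_id": p1, "gene_id": g})
        if g in two_probe:
            p2 = new_probe()
            probes_of[g].append((p2, 0.6))
            probe_rows.append({"probe_id": p2, "gene_id": g})
    for a, b in shared_pairs:
        p = probes_of[a][0][0]
        probe_rows.append({"probe_id": p, "gene_id": b})
        probes_of[b] = [(p, 1.0)]
    probemap = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])

    # --- developmental matrix ----------------------------------------------
    probe_ids: List[str] = []
    probe_gene: List[str] = []
    probe_affinity: List[float] = []
    emitted = set()
    for g in genes:
        for p, aff in probes_of.get(g, []):
            if p in emitted:
                continue
            emitted.add(p)
            probe_ids.append(p)
            probe_gene.append(g)
            probe_affinity.append(aff)

    aff = np.array(probe_affinity)[:, None]
    probe_true = true_mean[[gene_index[g] for g in probe_gene]] * aff
    n_rep = config.n_replicates
    cols, col_meta = [], []
    data = np.empty((len(probe_ids), n_t * n_rep))
    for t_i, stage in enumerate(stages):
        for r in range(1, n_rep + 1):
            noise = rng.normal(0.0, config.replicate_noise_sd, size=len(probe_ids))
            data[:, len(cols)] = probe_true[:, t_i] * np.exp(noise)
            cols.append(f"{stage}_r{r}")
            col_meta.append({"sample_id": f"{stage}_r{r}", "condition": stage,
                             "replicate": r, "treatment": ""})
    values = pd.DataFrame(data, index=probe_ids, columns=cols)
    flag_grid = np.where(
        probe_true < config.absent_threshold, "A",
        np.where(probe_true < config.marginal_threshold, "M", "P"),
    )
    flags = pd.DataFrame(
        np.repeat(flag_grid, n_rep, axis=1), index=probe_ids, columns=cols
    )
    samples = pd.DataFrame(col_meta).set_index("sample_id")
    developmental = ExpressionMatrix(values, samples, flags)

    # --- hormone matrix -----------------------------------------------------
    conditions = ["CK"] + list(config.hormone_treatments)
    responder_fold = {}
    for t, entries in truth.hormone_responders.items():
        for g, direction in entries:
            responder_fold[(g, t)] = config.de_fold if direction == "up" else 1.0 / config.de_fold
    h_true = np.empty((len(probe_ids), len(conditions)))
    for c_i, cond in enumerate(conditions):
        for p_i, g in enumerate(probe_gene):
            fold = responder_fold.get((g, cond), 1.0) if cond != "CK" else 1.0
            h_true[p_i, c_i] = baseline[g] * probe_affinity[p_i] * fold
    h_cols, h_meta = [], []
    h_data = np.empty((len(probe_ids), len(conditions) * n_rep))
    for c_i, cond in enumerate(conditions):
        for r in range(1, n_rep + 1):
            noise = rng.normal(0.0, config.replicate_noise_sd, size=len(probe_ids))
            h_data[:, len(h_cols)] = h_true[:, c_i] * np.exp(noise)
            h_cols.append(f"{cond}_r{r}")
            h_meta.append({"sample_id": f"{cond}_r{r}", "condition": cond,
                           "replicate": r, "treatment": cond if cond != "CK" else ""})
    h_values = pd.DataFrame(h_data, index=probe_ids, columns=h_cols)
    h_flag_grid = np.where(
        h_true < config.absent_threshold, "A",
        np.where(h_true < config.marginal_threshold, "M", "P"),
    )
    h_flags = pd.DataFrame(
        np.repeat(h_flag_grid, n_rep, axis=1), index=probe_ids, columns=h_cols
    )
    h_samples = pd.DataFrame(h_meta).set_index("sample_id")
    hormone = ExpressionMatrix(h_values, h_samples, h_flags)
    return developmental, hormone, probemap


# ---------------------------------------------------------------------------
# annotation, motifs, promoters
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimConfig, truth: GroundTruth
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, str]]:
    """Term annotation with planted enrichment, motif library and promoters."""
    config.validate()
    if not truth.all_gene_ids:
        raise ConfigError("truth carries no gene ids; generate the genome first")
    rng = np.random.default_rng([3, config.seed])
    genes = list(truth.all_gene_ids)

    # flat term table: every gene gets 1-3 background terms
    n_bg_terms = 30
    bg_terms = [f"TERM:{i:04d}" for i in range(1, n_bg_terms + 1)]
    rows = []
    for g in genes:
        for t in rng.choice(bg_terms, size=int(rng.integers(1, 4)), replace=False):
            rows.append({"gene_id": g, "term_id": t, "term_name": f"background process {t[-4:]}",
                         "namespace": "P"})
    # planted enriched term per module: most module members, few others
    module_members: Dict[int, List[str]] = {}
    for g, m in truth.module_of.items():
        module_members.setdefault(m, []).append(g)
    for m, members in sorted(module_members.items()):
        term = f"TERM:MOD{m:02d}"
        truth.enriched_terms[m] = [term]
        for g in members:
            if rng.random() < 0.85:
                rows.append({"gene_id": g, "term_id": term,
                             "term_name": f"planted module process {m}", "namespace": "P"})
        others = [g for g in genes if truth.module_of.get(g) != m]
        for g in rng.choice(others, size=max(2, int(0.02 * len(others))), replace=False):
            rows.append({"gene_id": g, "term_id": term,
                         "term_name": f"planted module process {m}", "namespace": "P"})
    terms = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "namespace"]).drop_duplicates()

    motif_library = pd.DataFrame(
        MOTIF_LIBRARY_ROWS, columns=["name", "pattern", "hormone_class"]
    )

    # promoters: one per family gene, 2 kb, with elements planted in the
    # promoters of hormone responders according to the responding hormone class
    from .promoter import IUPAC, reverse_complement

    responders: Dict[str, Set[str]] = {}
    for t, entries in truth.hormone_responders.items():
        for g, _ in entries:
            responders.setdefault(g, set()).add(t)
    promoters: Dict[str, str] = {}
    fam = sorted(truth.family_gene_ids, key=lambda g: int(g[1:]))
    L = config.promoter_length
    for g in fam:
        seq = list("".join(rng.choice(list(DNA), size=L)))
        planted: List[Tuple[str, str, int]] = []
        classes = {_HORMONE_CLASS.get(t) for t in responders.get(g, set())}
        pos = 100
        for _, row in motif_library.iterrows():
            if row["hormone_class"] not in classes:
                continue
            realization = "".join(
                sorted(IUPAC[c])[int(rng.integers(len(IUPAC[c])))] for c in row["pattern"]
            )
            strand = "+" if rng.random() < 0.5 else "-"
            insert = realization if strand == "+" else reverse_complement(realization)
            seq[pos - 1 : pos - 1 + len(insert)] = list(insert)
            planted.append((row["name"], strand, pos))
            pos += 60
        promoters[g] = "".join(seq)
        if planted:
            truth.planted_motifs[g] = planted
    return terms, motif_library, promoters


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    gene_models: List[GeneModel]
    proteins: Dict[str, str]
    domain_hits: List[DomainHit]
    truth: GroundTruth
    developmental: ExpressionMatrix
    hormone: ExpressionMatrix
    probemap: pd.DataFrame
    terms: pd.DataFrame
    motif_library: pd.DataFrame
    promoters: Dict[str, str]

    @property
    def node_classes(self) -> Dict[str, str]:
        return dict(self.truth.node_class_of)


def generate_all(config: Optional[SimConfig] = None) -> SyntheticDataset:
    """Generate the complete synthetic dataset for a configuration."""
    config = (config or SimConfig()).validate()
    models, proteins, hits, truth = generate_genome(config)
    developmental, hormone, probemap = generate_expression(config, truth)
    terms, motifs, promoters = generate_annotation(config, truth)
    return SyntheticDataset(
        config, models, proteins, hits, truth, developmental, hormone,
        probemap, terms, motifs, promoters,
    )
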