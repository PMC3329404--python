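"""Readers and writers for every external format the pipeline touches.

All tabular formats are TSV (decimal point, no thousands separators); genome
annotation is a GFF3 subset with ``gene``/``mRNA`` features and 1-based
inclusive coordinates. Readers validate loudly; every writer/reader pair is an
identity on valid data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed external input."""


AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene locus with 1-based inclusive coordinates and its transcripts.

    ``transcripts`` holds ``(transcript_id, protein_length_aa)`` pairs.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: List[Tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        tids = [t for t, _ in self.transcripts]
        if len(tids) != len(set(tids)):
            raise FormatError(f"gene {self.gene_id}: duplicate transcript ids")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainHit:
    """One domain annotation on a protein (1-based inclusive aa coordinates)."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    source: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"domain {self.domain_name} on {self.protein_id}: bad span "
                f"{self.start}-{self.end}"
            )
        if self.source not in {"smart", "pfam", "builtin"}:
            raise FormatError(f"unknown domain source {self.source!r}")


class ExpressionMatrix:
    """A signal matrix with per-sample metadata and optional P/M/A flags.

    ``values``: DataFrame, rows are gene or probe ids, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``condition``
    (tissue/stage or treatment label), ``replicate`` and optionally
    ``treatment``. ``flags``: optional DataFrame of {P, M, A} aligned with
    ``values``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        flags: Optional[pd.DataFrame] = None,
    ) -> None:
        if values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        if (values.to_numpy() <= 0).any():
            raise FormatError("expression signals must be > 0")
        missing = [c for c in values.columns if c not in samples.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        if "condition" not in samples.columns or "replicate" not in samples.columns:
            raise FormatError("sample metadata needs 'condition' and 'replicate'")
        if flags is not None:
            if flags.shape != values.shape or list(flags.columns) != list(
                values.columns
            ) or list(flags.index) != list(values.index):
                raise FormatError("flags table does not align with the signal matrix")
            bad = set(flags.to_numpy().ravel()) - {"P", "M", "A"}
            if bad:
                raise FormatError(f"illegal detection flags: {sorted(bad)}")
        self.values = values
        self.samples = samples.loc[list(values.columns)]
        self.flags = flags

    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def columns_for(self, condition: str) -> List[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        return list(sel)

    def condition_means(self) -> pd.DataFrame:
        """Replicate-averaged raw signals, one column per condition."""
        cols = {c: self.values[self.columns_for(c)].mean(axis=1) for c in self.conditions}
        return pd.DataFrame(cols)

    def subset_rows(self, ids: Sequence[str]) -> "ExpressionMatrix":
        flags = self.flags.loc[list(ids)] if self.flags is not None else None
        return ExpressionMatrix(self.values.loc[list(ids)], self.samples, flags)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, mode: str = "protein") -> List[SeqRecord]:
    """Read a FASTA file, validating ids and the declared alphabet.

    Record ids are the first whitespace token of the header; sequences are
    upper-cased. ``mode`` is ``protein`` or ``dna``.
    """
    alphabet = AMINO_ALPHABET if mode == "protein" else DNA_ALPHABET
    records: List[SeqRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        illegal = set(seq) - alphabet
        if illegal:
            raise FormatError(
                f"record {rec.id!r}: characters {sorted(illegal)} not in {mode} alphabet"
            )
        records.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    return records


def write_fasta(records: Iterable, path) -> None:
    recs = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            recs.append(SeqRecord(Seq(str(rec.seq)), id=rec.id, description=""))
        else:
            rid, seq = rec
            recs.append(SeqRecord(Seq(str(seq)), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _natural_key(label: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", label)]


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from a GFF3 subset or a 6-column TSV.

    The GFF3 subset carries ``gene`` features (``ID=``) and ``mRNA`` features
    (``ID=``, ``Parent=``); protein lengths ride on the mRNA ``protein_length``
    attribute. The TSV dialect has columns gene_id, chromosome, start, end,
    strand, transcripts ("tid:aa,tid:aa" or empty). Models are returned sorted
    by (chromosome natural order, start).
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    is_gff = first.startswith("##gff") or len(first.rstrip("\n").split("\t")) == 9
    models = _read_gff(path) if is_gff else _read_gene_tsv(path)
    models.sort(key=lambda m: (_natural_key(m.chromosome), m.start))
    return models


def _read_gff(path) -> List[GeneModel]:
    genes = {}
    mrnas = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr = dict(_GFF_ATTR.findall(attrs))
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{ln}: gene feature without ID")
                genes[gid] = GeneModel(gid, chrom, int(start), int(end), strand)
            elif ftype == "mRNA":
                mrnas.append((attr.get("Parent"), attr.get("ID"),
                              int(attr.get("protein_length", 0)), ln))
    for parent, tid, plen, ln in mrnas:
        if parent not in genes:
            raise FormatError(f"{path}:{ln}: mRNA {tid} has unknown Parent {parent}")
        genes[parent].transcripts.append((tid, plen))
    return list(genes.values())


def _read_gene_tsv(path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    if not required <= set(df.columns):
        raise FormatError(f"gene TSV missing columns {sorted(required - set(df.columns))}")
    models = []
    for row in df.itertuples(index=False):
        transcripts = []
        raw = getattr(row, "transcripts", "") or ""
        if isinstance(raw, str) and raw:
            for tok in raw.split(","):
                tid, aa = tok.split(":")
                transcripts.append((tid, int(aa)))
        models.append(
            GeneModel(row.gene_id, row.chromosome, int(row.start), int(row.end),
                      row.strand, transcripts)
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    """Write gene models as the GFF3 subset this package reads back."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chromosome}\tfamsurvey\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for tid, plen in m.transcripts:
                fh.write(
                    f"{m.chromosome}\tfamsurvey\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                    f"ID={tid};Parent={m.gene_id};protein_length={plen}\n"
                )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path, metadata_path, flags_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, samples, flags)


def write_expression(matrix: ExpressionMatrix, path, metadata_path, flags_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    matrix.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")
    if flags_path is not None and matrix.flags is not None:
        matrix.flags.to_csv(flags_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# small TSV tables
# ---------------------------------------------------------------------------

def read_domain_table(path) -> List[DomainHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        score = None if pd.isna(getattr(row, "score", None)) else float(row.score)
        hits.append(DomainHit(row.protein_id, row.domain_name, int(row.start),
                              int(row.end), row.source, score))
    return hits


def write_domain_table(hits: Sequence[DomainHit], path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "domain_name": h.domain_name,
                "start": h.start,
                "end": h.end,
                "source": h.source,
                "score": h.score,
            }
            for h in hits
        ],
        columns=["protein_id", "domain_name", "start", "end", "source", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise FormatError("probe map needs columns probe_id, gene_id")
    return df


def read_motif_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "pattern"} <= set(df.columns):
        raise FormatError("motif library needs columns name, pattern")
    return df


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise FormatError("annotation table needs columns gene_id, term_id")
    return df


def read_blocks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"block_id", "chrA", "startA", "endA", "chrB", "startB", "endB"}
    if not required <= set(df.columns):
        raise FormatError(f"blocks TSV missing columns {sorted(required - set(df.columns))}")
    return df


# ---------------------------------------------------------------------------
# network edge list
# ---------------------------------------------------------------------------

def write_network(edges: Iterable, path) -> None:
    """Write co-expression edges as a Cytoscape-importable TSV.

    Each unordered pair appears once; columns are source, target, pcc,
    p_value, n. Accepts edge objects with those attributes or 5-tuples.
    """
    rows = {}
    for e in edges:
        if hasattr(e, "gene_a"):
            a, b, r, p, n = e.gene_a, e.gene_b, e.pcc, e.p_value, e.n
        else:
            a, b, r, p, n = e
        key = (a, b) if a <= b else (b, a)
        rows[key] = (key[0], key[1], r, p, n)
    df = pd.DataFrame(
        sorted(rows.values()), columns=["source", "target", "pcc", "p_value", "n"]
    )
    df.to_csv(path, sep="\t", index=False)
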