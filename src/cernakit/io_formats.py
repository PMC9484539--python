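"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* GTF is 1-based inclusive; BED-like junction files are 0-based
  half-open with a strand column. Conversion to the 1-based inclusive
  internal convention happens exactly once, at read time.
* All readers reject malformed input (with coordinates where possible)
  rather than silently coercing it.
* The miRNA–target table loader accepts both a validated-interaction
  dialect (miRTarBase-like) and a predicted-interaction dialect
  (TargetScan-like), normalised to one schema with provenance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import ExpressionMatrix, ValidationError


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# gene models (GTF)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene as an ordered list of exons, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    exons: list  # list of (start, end), sorted, non-overlapping
    biotype: str = "other"

    def __post_init__(self) -> None:
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if s > e:
                raise ValidationError(
                    f"gene {self.gene_id}: exon start {s} > end {e}"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list:
        """Intervals strictly between consecutive exons (1-based incl.)."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


def read_gtf(path: str) -> list:
    """Parse a GTF file into :class:`GeneModel` objects.

    Exon records are grouped per ``gene_id``; coordinates stay 1-based
    inclusive. A line lacking a ``gene_id`` attribute raises
    :class:`ParseError` naming the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if "gene_id" not in fields[8]:
                raise ParseError(
                    f"{path}:{lineno}: missing gene_id attribute"
                )
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict = {}
    info: dict = {}
    for feat in db.all_features():
        gid = feat.attributes["gene_id"][0]
        biotype = "other"
        for key in ("gene_type", "gene_biotype"):
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        if gid not in info:
            info[gid] = (feat.seqid, feat.strand, biotype)
        if feat.featuretype == "exon":
            exons.setdefault(gid, []).append((feat.start, feat.end))
    genes = []
    for gid, (chrom, strand, biotype) in info.items():
        ex = exons.get(gid)
        if not ex:
            continue
        genes.append(GeneModel(gid, chrom, strand, ex, biotype))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "cernakit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# count matrices and sample metadata
# ---------------------------------------------------------------------------

def read_counts(path: str, meta_path: str | None = None,
                feature_meta_path: str | None = None) -> ExpressionMatrix:
    """Load a features-by-samples count TSV (first column = feature id).

    Every body cell must be a non-negative integer; violations raise
    :class:`ValidationError` with the offending coordinates. When
    ``meta_path`` is given, every matrix sample must appear in it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature ID {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(t, np.number) for t in df.dtypes]
        ][0]
        raise ValidationError(f"{path}: non-numeric cell in column {bad!r}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{path}: negative count at ({df.index[i]!r}, {df.columns[j]!r})"
        )
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValidationError(
            f"{path}: non-integer count at ({df.index[i]!r}, {df.columns[j]!r})"
        )
    sample_meta = None
    if meta_path is not None:
        sample_meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        missing = df.columns.difference(sample_meta.index)
        if len(missing):
            raise ValidationError(
                f"sample {missing[0]!r} missing from {meta_path}"
            )
    feature_meta = None
    if feature_meta_path is not None:
        feature_meta = pd.read_csv(feature_meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(np.int64), feature_meta, sample_meta)


def write_counts(matrix: ExpressionMatrix, path: str) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label)


# ---------------------------------------------------------------------------
# back-splice junctions (BED-like TSV)
# ---------------------------------------------------------------------------

def read_junctions(path: str):
    """Read back-splice junctions from a 6-column BED-like TSV.

    Columns: chrom, start (0-based), end (half-open), circ_id,
    read_support, strand. Coordinates are converted to 1-based
    inclusive at read time.
    """
    from .circ_annot import CircJunction

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, name, score, strand = f[:6]
            out.append(
                CircJunction(
                    circ_id=name,
                    chrom=chrom,
                    start=int(start) + 1,  # 0-based -> 1-based
                    end=int(end),          # half-open -> inclusive
                    strand=strand,
                    read_support=int(score),
                )
            )
    return out


def write_junctions(junctions, path: str) -> None:
    """Write junctions as 6-column BED-like TSV (0-based half-open)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.start - 1}\t{j.end}\t{j.circ_id}\t"
                f"{j.read_support}\t{j.strand}\n"
            )


# ---------------------------------------------------------------------------
# sequences (FASTA)
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict:
    """FASTA -> {id: uppercase RNA/DNA string}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(sequences: dict, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# external miRNA-target tables
# ---------------------------------------------------------------------------

#: column aliases for the two supported dialects
_VALIDATED_COLS = {"mirna": "miRNA", "target": "Target Gene"}
_PREDICTED_COLS = {"mirna": "miR Family", "target": "Gene Symbol"}


def read_target_table(path: str, source: str | None = None) -> pd.DataFrame:
    """Load a miRNA–target interaction TSV into the normalised schema.

    Accepts either a validated-interaction dialect (columns ``miRNA``,
    ``Target Gene``), a predicted-interaction dialect (``miR Family``,
    ``Gene Symbol``), or the already-normalised schema (``mirna_id``,
    ``target_id``[, ``evidence``, ``source``]). Duplicate
    (miRNA, target, source) rows are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"mirna_id", "target_id"} <= cols:
        out = df.copy()
        if "evidence" not in out:
            out["evidence"] = "validated"
        if "source" not in out:
            out["source"] = source or "user"
    elif {_VALIDATED_COLS["mirna"], _VALIDATED_COLS["target"]} <= cols:
        out = pd.DataFrame(
            {
                "mirna_id": df[_VALIDATED_COLS["mirna"]],
                "target_id": df[_VALIDATED_COLS["target"]],
                "evidence": "validated",
                "source": source or "mirtarbase_like",
            }
        )
    elif {_PREDICTED_COLS["mirna"], _PREDICTED_COLS["target"]} <= cols:
        out = pd.DataFrame(
            {
                "mirna_id": df[_PREDICTED_COLS["mirna"]],
                "target_id": df[_PREDICTED_COLS["target"]],
                "evidence": "predicted",
                "source": source or "targetscan_like",
            }
        )
    else:
        raise ParseError(
            f"{path}: unrecognised target-table dialect (columns {sorted(cols)})"
        )
    out = out.drop_duplicates(subset=["mirna_id", "target_id", "source"])
    return out.reset_index(drop=True)


def merge_target_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of normalised target tables, provenance preserved.

    A (miRNA, target) pair present in several sources keeps one row per
    source; downstream candidate building collapses them with merged
    evidence.
    """
    merged = pd.concat(tables, ignore_index=True)
    return merged.drop_duplicates(
        subset=["mirna_id", "target_id", "source"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# NTP signatures and GMT gene sets
# ---------------------------------------------------------------------------

def read_signatures(path: str):
    """TSV (class, gene_id, sign) -> list of TemplateSignature."""
    from .ntp import TemplateSignature

    df = pd.read_csv(path, sep="\t")
    required = {"class", "gene_id", "sign"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("class", sort=False):
        genes = list(zip(grp["gene_id"], grp["sign"].astype(int)))
        out.append(TemplateSignature(str(label), genes))
    return out


def write_signatures(templates, path: str) -> None:
    rows = [
        {"class": t.class_label, "gene_id": g, "sign": s}
        for t in templates
        for g, s in t.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict:
    """GMT -> {set_id: [gene, ...]} (description column discarded)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs id, description, genes"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def read_survival(path: str) -> pd.DataFrame:
    """TSV (sample, time, event) with time > 0 and event in {0, 1}."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample"].iloc[0]
        raise ValidationError(f"{path}: non-positive time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event column must be 0/1")
    return df.set_index("sample")


# ---------------------------------------------------------------------------
# ceRNA network serialisation
# ---------------------------------------------------------------------------

_EDGE_COLS = [
    "cerna_id", "cerna_class", "mrna_id", "k", "K", "n", "N",
    "p_hyper", "pcc", "shared_mirnas",
]


def write_network(edges, path: str, format: str = "tsv") -> None:
    """Serialise ceRNA edges as TSV or GraphML.

    TSV: one row per edge, shared miRNA IDs semicolon-joined.
    GraphML: nodes carry ``node_class`` (lncRNA/circRNA/mRNA)
    attributes; edges carry the hypergeometric p, PCC and shared count.
    """
    rows = [
        {
            "cerna_id": e.cerna_id,
            "cerna_class": e.cerna_class,
            "mrna_id": e.mrna_id,
            "k": e.k,
            "K": e.K,
            "n": e.n,
            "N": e.N,
            "p_hyper": e.p_hyper,
            "pcc": e.pcc,
            "shared_mirnas": ";".join(e.shared_mirnas),
        }
        for e in edges
    ]
    if format == "tsv":
        pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.Graph()
        for e in edges:
            g.add_node(e.cerna_id, node_class=e.cerna_class)
            g.add_node(e.mrna_id, node_class="mRNA")
            g.add_edge(
                e.cerna_id,
                e.mrna_id,
                p_hyper=float(e.p_hyper),
                pcc=float(e.pcc),
                shared=int(e.k),
                shared_mirnas=";".join(e.shared_mirnas),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["shared_mirnas"] = df["shared_mirnas"].fillna("").map(
        lambda s: s.split(";") if s else []
    )
    return df
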