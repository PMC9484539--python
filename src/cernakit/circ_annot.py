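"""Genomic-origin classification of circRNA back-splice junctions.

A back-splice junction is the non-canonical splice joining a
downstream donor to an upstream acceptor; its two breakpoints are
compared with gene annotation to call the circRNA's origin:

* **exonic** — both breakpoints lie within ``slack`` bp of annotated
  exon boundaries of one gene on the matching strand (junction start
  vs an exon start, junction end vs an exon end);
* **intronic** — the full span lies strictly inside a single intron of
  one gene;
* **intergenic** — the span overlaps no gene on its strand (antisense
  overlap counts as intergenic: splice-site annotation is
  strand-specific).

A junction overlapping a gene but matching neither rule (e.g. one
breakpoint in an exon interior) falls back to exonic when either
breakpoint touches an exon, else intronic — the dominant-category
convention; such calls carry ``fallback=True``. The partition is
exhaustive and exclusive: every junction receives exactly one origin.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .matrix import ValidationError

ORIGINS = ("exonic", "intronic", "intergenic")


@dataclass
class CircJunction:
    """Back-splice junction, 1-based inclusive coordinates.

    ``start`` is the acceptor (upstream) coordinate, ``end`` the donor
    (downstream) coordinate; start < end on the genome.
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    read_support: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"junction {self.circ_id}: start must be < end"
            )
        if self.read_support < 0:
            raise ValidationError(
                f"junction {self.circ_id}: negative read support"
            )


@dataclass
class OriginCall:
    circ_id: str
    origin: str
    host_gene: str | None = None
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(f"unknown origin {self.origin!r}")
        if (self.host_gene is None) != (self.origin == "intergenic"):
            raise ValidationError(
                f"{self.circ_id}: host_gene must be set iff not intergenic"
            )


def _index_genes(genes) -> dict:
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    return by_chrom


def classify_origin(junction: CircJunction, genes, slack: int = 0) -> OriginCall:
    """Call the origin of one junction against a gene-model set."""
    return classify_origins([junction], genes, slack=slack)[0]


def classify_origins(junctions, genes, slack: int = 0) -> list:
    """Vector version of :func:`classify_origin`."""
    by_chrom = _index_genes(genes)
    warned_chroms = set()
    calls = []
    for j in junctions:
        if j.chrom not in by_chrom:
            if j.chrom not in warned_chroms:
                warnings.warn(
                    f"junction chromosome {j.chrom!r} absent from the "
                    "annotation; calling intergenic"
                )
                warned_chroms.add(j.chrom)
            calls.append(OriginCall(j.circ_id, "intergenic"))
            continue
        overlapping = [
            g
            for g in by_chrom[j.chrom]
            if g.strand == j.strand and g.start <= j.end and j.start <= g.end
        ]
        calls.append(_classify_one(j, overlapping, slack))
    return calls


def _classify_one(j: CircJunction, overlapping, slack: int) -> OriginCall:
    if not overlapping:
        return OriginCall(j.circ_id, "intergenic")
    # exonic: both breakpoints on exon boundaries of one gene
    for g in overlapping:
        start_ok = any(abs(j.start - s) <= slack for s, _ in g.exons)
        end_ok = any(abs(j.end - e) <= slack for _, e in g.exons)
        if start_ok and end_ok:
            return OriginCall(j.circ_id, "exonic", g.gene_id)
    # intronic: full span strictly inside one intron
    for g in overlapping:
        for s, e in g.introns:
            if s <= j.start and j.end <= e:
                return OriginCall(j.circ_id, "intronic", g.gene_id)
    # fallback: dominant category when a breakpoint touches an exon
    for g in overlapping:
        touches = any(
            s <= pos <= e
            for pos in (j.start, j.end)
            for s, e in g.exons
        )
        if touches:
            return OriginCall(j.circ_id, "exonic", g.gene_id, fallback=True)
    return OriginCall(j.circ_id, "intronic", overlapping[0].gene_id,
                      fallback=True)


def origin_fractions(calls) -> pd.Series:
    """Fraction of junctions per origin class (sums to 1)."""
    counts = Counter(c.origin for c in calls)
    total = sum(counts.values())
    return pd.Series(
        {o: counts.get(o, 0) / total if total else 0.0 for o in ORIGINS},
        name="fraction",
    )


def alt_circularization(calls, k: int = 2) -> tuple:
    """Per-host-gene isoform counts and the multi-isoform fraction.

    Counts circRNA isoforms per host gene (exonic + intronic calls)
    and reports the fraction of host genes producing at least ``k``
    isoforms (default 2 — the minimal evidence of alternative
    circularization; use k=3 for a strict more-than-two reading).
    """
    per_gene = Counter(
        c.host_gene for c in calls if c.host_gene is not None
    )
    counts = pd.Series(per_gene, dtype=int).sort_index()
    if len(counts) == 0:
        return counts, 0.0
    frac = float((counts >= k).mean())
    return counts, frac


def origin_table(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ_id": c.circ_id,
                "origin": c.origin,
                "host_gene": c.host_gene if c.host_gene is not None else "",
                "fallback": c.fallback,
            }
            for c in calls
        ]
    )
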