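"""Gene models and the splicing-event universe.

A gene is a single transcript model: an ordered list of non-overlapping
exons on one strand.  Introns are the regions between consecutive exons.
Every intron defines one intron-retention (IR) event; every internal exon
(an exon with at least one exon on each side) defines one exon-skipping
(ES) event.

Coordinates are 0-based half-open internally.  GFF3 I/O converts to and
from that format's 1-based inclusive convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
import pandas as pd

__all__ = [
    "AnnotationError",
    "Exon",
    "Intron",
    "Gene",
    "read_gff3",
    "write_gff3",
    "derive_events",
]

_STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed gene models (overlapping exons, bad strand...)."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"exon must satisfy 0 <= start < end, got ({self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Intron:
    """The region between two consecutive exons of one gene."""

    gene_id: str
    index: int  # 0-based position within the gene, 5'-most first in genome order
    chrom: str
    start: int  # == previous exon's end
    end: int    # == next exon's start
    strand: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise AnnotationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon on different chrom/strand"
                )
            if ex.start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at {ex.start}"
                )
            prev_end = ex.end

    @property
    def introns(self) -> tuple[Intron, ...]:
        return tuple(
            Intron(self.gene_id, i, self.chrom, a.end, b.start, self.strand)
            for i, (a, b) in enumerate(zip(self.exons, self.exons[1:]))
        )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


def _gene_from_rows(gene_id: str, chrom: str, strand: str,
                    exon_rows: list[tuple[int, int]]) -> Gene:
    exon_rows = sorted(exon_rows)
    exons = tuple(Exon(chrom, s, e, strand) for s, e in exon_rows)
    return Gene(gene_id, chrom, strand, exons)


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Read gene models from GFF3 (gene features with exon children).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Genes whose exons overlap, or with a strand other than +/-, are rejected
    with an :class:`AnnotationError` naming the gene.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        if g.strand not in _STRANDS:
            raise AnnotationError(f"gene {g.id}: unknown strand {g.strand!r}")
        exon_rows = [
            (child.start - 1, child.end)
            for child in db.children(g, featuretype="exon")
        ]
        if not exon_rows:
            raise AnnotationError(f"gene {g.id}: no exon features")
        genes.append(_gene_from_rows(g.id, g.seqid, g.strand, exon_rows))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: list[Gene], path: str | os.PathLike,
               source: str = "retronaut") -> None:
    """Write gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def derive_events(genes: list[Gene]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the IR and ES event universe from gene models.

    Returns
    -------
    ir_events : DataFrame
        One row per intron: event_id, gene_id, index, chrom, start, end,
        strand.  ``start``/``end`` are the intron coordinates; the exon-exon
        splice junction of the event is exactly this interval.
    es_events : DataFrame
        One row per internal exon: event_id, gene_id, index, chrom,
        exon_start, exon_end, strand, plus the two inclusion junctions
        (inc1_* = upstream intron in genome order, inc2_* = downstream) and
        the skipping junction (skip_* spans from the end of the previous
        exon to the start of the next).
    """
    ir_rows = []
    es_rows = []
    for g in genes:
        for intr in g.introns:
            ir_rows.append(
                dict(
                    event_id=f"{g.gene_id}.I{intr.index}",
                    gene_id=g.gene_id,
                    index=intr.index,
                    chrom=g.chrom,
                    start=intr.start,
                    end=intr.end,
                    strand=g.strand,
                )
            )
        for i in range(1, len(g.exons) - 1):
            prev_e, ex, next_e = g.exons[i - 1], g.exons[i], g.exons[i + 1]
            es_rows.append(
                dict(
                    event_id=f"{g.gene_id}.E{i}",
                    gene_id=g.gene_id,
                    index=i,
                    chrom=g.chrom,
                    exon_start=ex.start,
                    exon_end=ex.end,
                    strand=g.strand,
                    inc1_start=prev_e.end,
                    inc1_end=ex.start,
                    inc2_start=ex.end,
                    inc2_end=next_e.start,
                    skip_start=prev_e.end,
                    skip_end=next_e.start,
                )
            )
    ir_cols = ["event_id", "gene_id", "index", "chrom", "start", "end", "strand"]
    es_cols = [
        "event_id", "gene_id", "index", "chrom", "exon_start", "exon_end",
        "strand", "inc1_start", "inc1_end", "inc2_start", "inc2_end",
        "skip_start", "skip_end",
    ]
    ir = pd.DataFrame(ir_rows, columns=ir_cols)
    es = pd.DataFrame(es_rows, columns=es_cols)
    return ir, es
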