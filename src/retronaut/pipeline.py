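"""End-to-end orchestration: simulate -> count -> diffsplice -> dge -> report.

Two entry points: :func:`run_in_memory` keeps everything as in-memory
objects (fast, used for large statistical checks), and
:func:`run_to_files` routes the same pipeline through its on-disk
formats (FASTA/GFF3/SAM/TSV/JSON) so runs are reproducible artefacts;
with a fixed config seed the emitted files are byte-identical across
runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from . import io as rio
from .annotation import Gene, derive_events, read_gff3, write_gff3
from .counting import (
    DEFAULT_MIN_OVERHANG,
    JunctionCounts,
    JunctionIndex,
    count_junctions,
)
from .dge import test_dge
from .reads import ReadTable
from .reporting import SummaryReport, ma_table, summarize
from .simulate import (
    SimConfig,
    TruthTable,
    generate_annotation,
    make_truth,
    read_fasta,
    simulate_reads,
    write_fasta,
)
from .splicing import (
    DEFAULT_ALPHA,
    DEFAULT_DELTA_MIN,
    DEFAULT_MIN_READS,
    test_splicing,
)

__all__ = ["PipelineResult", "run_in_memory", "run_to_files"]


@dataclass
class PipelineResult:
    genes: list[Gene]
    truth: TruthTable
    design: pd.DataFrame
    reads: ReadTable
    counts: JunctionCounts
    ir_results: pd.DataFrame
    es_results: pd.DataFrame
    dge_results: pd.DataFrame
    summary: SummaryReport


def _analyse(
    genes: list[Gene],
    reads: ReadTable,
    design: pd.DataFrame,
    min_overhang: int,
    min_reads: int,
    alpha: float,
    delta_min: float,
) -> tuple[JunctionCounts, pd.DataFrame, pd.DataFrame, pd.DataFrame, SummaryReport]:
    ir_events, es_events = derive_events(genes)
    index = JunctionIndex.build(genes, ir_events, es_events)
    counts = count_junctions(reads, index, min_overhang=min_overhang)
    ir_res = test_splicing(
        counts.ir, design, "IR", events=ir_events,
        min_reads=min_reads, alpha=alpha, delta_min=delta_min,
    )
    es_res = test_splicing(
        counts.es, design, "ES", events=es_events,
        min_reads=min_reads, alpha=alpha, delta_min=delta_min,
    ) if len(es_events) else pd.DataFrame(
        columns=["event_id", "gene_id", "p", "p_adj", "delta",
                 "mean_log2_count", "classification"]
    )
    dge_res = test_dge(counts.gene, design, alpha=alpha)
    summary = summarize(ir_res, es_res if len(es_res) else None, dge_res)
    return counts, ir_res, es_res, dge_res, summary


def run_in_memory(
    config: SimConfig,
    truth: TruthTable | None = None,
    genes: list[Gene] | None = None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    delta_min: float = DEFAULT_DELTA_MIN,
) -> PipelineResult:
    """Run the whole pipeline without touching disk."""
    if genes is None:
        _, genes = generate_annotation(config)
    if truth is None:
        truth = make_truth(genes, config)
    reads, design = simulate_reads(config, genes, truth)
    counts, ir_res, es_res, dge_res, summary = _analyse(
        genes, reads, design, min_overhang, min_reads, alpha, delta_min
    )
    return PipelineResult(
        genes, truth, design, reads, counts, ir_res, es_res, dge_res, summary
    )


def run_to_files(
    config: SimConfig,
    outdir: str | os.PathLike,
    truth: TruthTable | None = None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    delta_min: float = DEFAULT_DELTA_MIN,
) -> PipelineResult:
    """Run the pipeline through its file formats under ``outdir``.

    Writes genome.fa, genes.gff3, one SAM per sample, design.tsv, the
    truth tables, the count TSVs, per-event/per-gene result TSVs, MA
    tables and summary.json — then reads each artefact back where the
    next stage consumes it, so the files are the actual data path.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)

    genome, genes = generate_annotation(config)
    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    write_gff3(genes, os.path.join(outdir, "genes.gff3"))
    if truth is None:
        truth = make_truth(genes, config)
    rio.write_truth(truth, outdir)

    reads, design = simulate_reads(config, genes, truth)
    rio.write_design(design, os.path.join(outdir, "design.tsv"))
    sam_dir = os.path.join(outdir, "reads")
    genome_rt = read_fasta(os.path.join(outdir, "genome.fa"))
    sam_paths = reads.to_sam(genome_rt, sam_dir)

    genes_rt = read_gff3(os.path.join(outdir, "genes.gff3"))
    reads_rt = ReadTable.from_sam(sam_paths)
    design_rt = rio.read_design(os.path.join(outdir, "design.tsv"))

    counts, ir_res, es_res, dge_res, summary = _analyse(
        genes_rt, reads_rt, design_rt, min_overhang, min_reads, alpha, delta_min
    )
    rio.write_counts(counts, os.path.join(outdir, "counts"))
    rio.write_tsv(ir_res, os.path.join(outdir, "ir_results.tsv"))
    rio.write_tsv(es_res, os.path.join(outdir, "es_results.tsv"))
    rio.write_tsv(dge_res, os.path.join(outdir, "dge_results.tsv"))
    rio.write_tsv(
        ma_table(ir_res, "splicing", delta_min),
        os.path.join(outdir, "ma_ir.tsv"),
    )
    if len(es_res):
        rio.write_tsv(
            ma_table(es_res, "splicing", delta_min),
            os.path.join(outdir, "ma_es.tsv"),
        )
    rio.write_tsv(ma_table(dge_res, "dge"), os.path.join(outdir, "ma_dge.tsv"))
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        fh.write(summary.to_json() + "\n")

    return PipelineResult(
        genes_rt, truth, design_rt, reads_rt, counts, ir_res, es_res,
        dge_res, summary,
    )
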