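"""Deterministic TSV readers/writers for the pipeline's tables."""

from __future__ import annotations

import os

import pandas as pd

from .counting import JunctionCounts
from .simulate import TruthTable

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_design(design: pd.DataFrame, path) -> None:
    write_tsv(design, path)


def read_design(path) -> pd.DataFrame:
    return read_tsv(path)


def write_counts(counts: JunctionCounts, outdir) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ir": os.path.join(str(outdir), "ir_counts.tsv"),
        "es": os.path.join(str(outdir), "es_counts.tsv"),
        "gene": os.path.join(str(outdir), "gene_counts.tsv"),
    }
    write_tsv(counts.ir, paths["ir"])
    write_tsv(counts.es, paths["es"])
    write_tsv(counts.gene, paths["gene"], index=True)
    return paths


def read_counts(outdir) -> JunctionCounts:
    return JunctionCounts(
        ir=read_tsv(os.path.join(str(outdir), "ir_counts.tsv")),
        es=read_tsv(os.path.join(str(outdir), "es_counts.tsv")),
        gene=read_tsv(
            os.path.join(str(outdir), "gene_counts.tsv"), index_col="gene_id"
        ),
    )


def write_truth(truth: TruthTable, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_tsv(truth.introns, os.path.join(str(outdir), "truth_introns.tsv"))
    write_tsv(truth.exons, os.path.join(str(outdir), "truth_exons.tsv"))
    write_tsv(truth.genes, os.path.join(str(outdir), "truth_genes.tsv"))


def read_truth(outdir) -> TruthTable:
    return TruthTable(
        introns=read_tsv(os.path.join(str(outdir), "truth_introns.tsv")),
        exons=read_tsv(os.path.join(str(outdir), "truth_exons.tsv")),
        genes=read_tsv(os.path.join(str(outdir), "truth_genes.tsv")),
    )
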