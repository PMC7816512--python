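"""Junction-level read counting.

Assignment rules
----------------
* A spliced read supports an exon-exon junction (EE / INC1 / INC2 / SKP)
  iff one of its splice gaps equals the junction's intron coordinates
  exactly, with at least ``min_overhang`` aligned bases on each side of
  the gap.
* A read supports an exon-intron boundary (EI5 / EI3) iff one of its
  aligned blocks covers the boundary position with at least
  ``min_overhang`` bases on each side.
* A read may support several junctions (e.g. both boundaries of a short
  retained intron), and the same genomic junction may feed several events
  (an intron's splice junction is also an inclusion junction of the
  neighbouring internal exon).
* The per-gene count is the number of reads whose leftmost aligned base
  falls inside the gene span.  Genes are assumed non-overlapping.

EI5/EI3 are the boundaries at the intron's transcriptional 5' and 3'
ends (so they swap genomic sides on the minus strand); the PIR statistic
is symmetric in the two, so this is labelling only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Gene
from .reads import Read, ReadTable

__all__ = ["JunctionIndex", "JunctionCounts", "assign_read", "count_junctions"]

DEFAULT_MIN_OVERHANG = 6

IR_CELLS = ("EE", "EI5", "EI3")
ES_CELLS = ("INC1", "INC2", "SKP")

_POS_BITS = 40  # boundary keys are chrom << 40 | position


@dataclass
class JunctionIndex:
    """Lookup structures mapping genomic junctions to event count cells."""

    chroms: list[str]
    ir_ids: list[str]
    es_ids: list[str]
    # splice-gap targets: one row per (gap, event-cell) pair
    gap_map: pd.DataFrame      # chrom, start, end, etype (0=IR,1=ES), row, col
    # exon-intron boundaries, sorted by encoded key
    boundary_keys: np.ndarray  # int64, chrom << POS_BITS | pos
    boundary_row: np.ndarray   # index into ir_ids
    boundary_col: np.ndarray   # 1 = EI5, 2 = EI3
    # gene spans, sorted by encoded start key
    gene_ids: list[str]
    gene_start_key: np.ndarray
    gene_end_key: np.ndarray
    gene_order: np.ndarray     # maps sorted position -> index into gene_ids

    @classmethod
    def build(cls, genes: list[Gene], ir_events: pd.DataFrame,
              es_events: pd.DataFrame) -> "JunctionIndex":
        chroms = sorted({g.chrom for g in genes})
        c_idx = {c: i for i, c in enumerate(chroms)}

        ir_ids = ir_events["event_id"].tolist()
        es_ids = es_events["event_id"].tolist()

        gap_rows = []
        b_keys, b_row, b_col = [], [], []
        for row_i, ev in enumerate(ir_events.itertuples(index=False)):
            cc = c_idx[ev.chrom]
            gap_rows.append((cc, ev.start, ev.end, 0, row_i, 0))  # EE
            five, three = (ev.start, ev.end) if ev.strand == "+" else (ev.end, ev.start)
            b_keys.append((cc << _POS_BITS) | five)
            b_row.append(row_i)
            b_col.append(1)  # EI5
            b_keys.append((cc << _POS_BITS) | three)
            b_row.append(row_i)
            b_col.append(2)  # EI3
        for row_i, ev in enumerate(es_events.itertuples(index=False)):
            cc = c_idx[ev.chrom]
            gap_rows.append((cc, ev.inc1_start, ev.inc1_end, 1, row_i, 0))  # INC1
            gap_rows.append((cc, ev.inc2_start, ev.inc2_end, 1, row_i, 1))  # INC2
            gap_rows.append((cc, ev.skip_start, ev.skip_end, 1, row_i, 2))  # SKP

        gap_map = pd.DataFrame(
            gap_rows, columns=["chrom", "start", "end", "etype", "row", "col"]
        )
        b_keys = np.asarray(b_keys, dtype=np.int64)
        order = np.argsort(b_keys, kind="stable")

        genes_sorted = sorted(genes, key=lambda g: (c_idx[g.chrom], g.start))
        gene_ids = [g.gene_id for g in genes_sorted]
        gsk = np.array(
            [(c_idx[g.chrom] << _POS_BITS) | g.start for g in genes_sorted],
            dtype=np.int64,
        )
        gek = np.array(
            [(c_idx[g.chrom] << _POS_BITS) | g.end for g in genes_sorted],
            dtype=np.int64,
        )
        return cls(
            chroms=chroms,
            ir_ids=ir_ids,
            es_ids=es_ids,
            gap_map=gap_map,
            boundary_keys=b_keys[order],
            boundary_row=np.asarray(b_row, dtype=np.int64)[order],
            boundary_col=np.asarray(b_col, dtype=np.int64)[order],
            gene_ids=gene_ids,
            gene_start_key=gsk,
            gene_end_key=gek,
            gene_order=np.arange(len(gene_ids)),
        )


@dataclass
class JunctionCounts:
    """Per-event, per-sample junction read counts plus per-gene totals."""

    ir: pd.DataFrame    # event_id, sample, EE, EI5, EI3
    es: pd.DataFrame    # event_id, sample, INC1, INC2, SKP
    gene: pd.DataFrame  # genes x samples (wide; index gene_id)


def assign_read(read: Read, index: JunctionIndex,
                min_overhang: int = DEFAULT_MIN_OVERHANG) -> set[tuple[str, str]]:
    """Assign a single read to junction cells.

    Returns a set of ``(event_id, cell)`` pairs where cell is one of
    EE/EI5/EI3 (IR events) or INC1/INC2/SKP (ES events).  A read that
    matches nothing yields the empty set.
    """
    try:
        cc = index.chroms.index(read.chrom)
    except ValueError:
        return set()
    hits: set[tuple[str, str]] = set()
    gm = index.gap_map
    blocks = read.blocks
    for (gs, ge), (ls, le), (rs, re) in zip(read.gaps, blocks, blocks[1:]):
        if le - ls < min_overhang or re - rs < min_overhang:
            continue
        match = gm[(gm["chrom"] == cc) & (gm["start"] == gs) & (gm["end"] == ge)]
        for t in match.itertuples(index=False):
            if t.etype == 0:
                hits.add((index.ir_ids[t.row], IR_CELLS[t.col]))
            else:
                hits.add((index.es_ids[t.row], ES_CELLS[t.col]))
    for (bs, be) in blocks:
        lo_key = (cc << _POS_BITS) | (bs + min_overhang)
        hi_key = (cc << _POS_BITS) | (be - min_overhang)
        if hi_key < lo_key:
            continue
        lo = np.searchsorted(index.boundary_keys, lo_key, side="left")
        hi = np.searchsorted(index.boundary_keys, hi_key, side="right")
        for k in range(lo, hi):
            hits.add(
                (
                    index.ir_ids[index.boundary_row[k]],
                    IR_CELLS[index.boundary_col[k]],
                )
            )
    return hits


def _chrom_remap(rt: ReadTable, index: JunctionIndex) -> np.ndarray:
    """Map table-local chromosome codes onto the index's coding (-1 = absent)."""
    lookup = {c: i for i, c in enumerate(index.chroms)}
    return np.array([lookup.get(c, -1) for c in rt.chroms], dtype=np.int64)


def _accumulate_gaps(rt: ReadTable, index: JunctionIndex, min_overhang: int,
                     ir_arr: np.ndarray, es_arr: np.ndarray,
                     cmap: np.ndarray) -> None:
    g = rt.gaps
    if len(g) == 0 or len(index.gap_map) == 0:
        return
    chrom = cmap[g["chrom"].to_numpy(np.int64)]
    ok = (
        (g["left"].to_numpy() >= min_overhang)
        & (g["right"].to_numpy() >= min_overhang)
        & (chrom >= 0)
    )
    g = g.loc[ok, ["sample", "start", "end"]].assign(chrom=chrom[ok])
    if len(g) == 0:
        return
    per_key = (
        g.groupby(["chrom", "start", "end", "sample"], sort=False)
        .size()
        .reset_index(name="n")
    )
    merged = per_key.merge(index.gap_map, on=["chrom", "start", "end"], how="inner")
    for etype, arr in ((0, ir_arr), (1, es_arr)):
        part = merged[merged["etype"] == etype]
        if len(part):
            np.add.at(
                arr,
                (
                    part["row"].to_numpy(),
                    part["sample"].to_numpy(),
                    part["col"].to_numpy(),
                ),
                part["n"].to_numpy(),
            )


def _accumulate_boundaries(rt: ReadTable, index: JunctionIndex,
                           min_overhang: int, ir_arr: np.ndarray,
                           cmap: np.ndarray) -> None:
    b = rt.blocks
    if len(b) == 0 or len(index.boundary_keys) == 0:
        return
    chrom = cmap[b["chrom"].to_numpy(np.int64)]
    known = chrom >= 0
    if not known.all():
        b = b.loc[known]
        chrom = chrom[known]
    bs = b["start"].to_numpy(np.int64)
    be = b["end"].to_numpy(np.int64)
    sample = b["sample"].to_numpy(np.int64)
    lo_key = (chrom << _POS_BITS) | (bs + min_overhang)
    hi_key = (chrom << _POS_BITS) + (be - min_overhang)
    lo = np.searchsorted(index.boundary_keys, lo_key, side="left")
    hi = np.searchsorted(index.boundary_keys, hi_key, side="right")
    hi = np.maximum(hi, lo)
    max_hits = int((hi - lo).max(initial=0))
    for k in range(max_hits):
        sel = (lo + k) < hi
        if not sel.any():
            break
        bidx = lo[sel] + k
        np.add.at(
            ir_arr,
            (index.boundary_row[bidx], sample[sel], index.boundary_col[bidx]),
            1,
        )


def _accumulate_genes(rt: ReadTable, index: JunctionIndex,
                      gene_arr: np.ndarray, cmap: np.ndarray) -> None:
    r = rt.reads
    if len(r) == 0 or len(index.gene_start_key) == 0:
        return
    chrom = cmap[r["chrom"].to_numpy(np.int64)]
    known = chrom >= 0
    key = (chrom[known] << _POS_BITS) | r["start"].to_numpy(np.int64)[known]
    sample = r["sample"].to_numpy(np.int64)[known]
    idx = np.searchsorted(index.gene_start_key, key, side="right") - 1
    valid = idx >= 0
    idx_c = np.clip(idx, 0, None)
    valid &= key < index.gene_end_key[idx_c]
    np.add.at(gene_arr, (idx_c[valid], sample[valid]), 1)


def count_junctions(rt: ReadTable, index: JunctionIndex,
                    min_overhang: int = DEFAULT_MIN_OVERHANG) -> JunctionCounts:
    """Count junction support for every event and total reads per gene.

    Equivalent to applying :func:`assign_read` to every read and tallying,
    but vectorised; counting is order-independent by construction.
    """
    n_samples = len(rt.samples)
    ir_arr = np.zeros((len(index.ir_ids), n_samples, 3), dtype=np.int64)
    es_arr = np.zeros((len(index.es_ids), n_samples, 3), dtype=np.int64)
    gene_arr = np.zeros((len(index.gene_ids), n_samples), dtype=np.int64)

    cmap = _chrom_remap(rt, index)
    _accumulate_gaps(rt, index, min_overhang, ir_arr, es_arr, cmap)
    _accumulate_boundaries(rt, index, min_overhang, ir_arr, cmap)
    _accumulate_genes(rt, index, gene_arr, cmap)

    def tidy(arr: np.ndarray, ids: list[str], cells: tuple[str, ...]) -> pd.DataFrame:
        n_ev = len(ids)
        out = pd.DataFrame(
            {
                "event_id": np.repeat(ids, n_samples),
                "sample": np.tile(rt.samples, n_ev),
            }
        )
        flat = arr.reshape(n_ev * n_samples, len(cells)) if n_ev else np.zeros(
            (0, len(cells)), dtype=np.int64
        )
        for j, cell in enumerate(cells):
            out[cell] = flat[:, j]
        return out

    gene = pd.DataFrame(gene_arr, index=index.gene_ids, columns=rt.samples)
    gene.index.name = "gene_id"
    return JunctionCounts(
        ir=tidy(ir_arr, index.ir_ids, IR_CELLS),
        es=tidy(es_arr, index.es_ids, ES_CELLS),
        gene=gene,
    )
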