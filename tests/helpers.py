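"""Independent oracles used by the test suite.

Everything here is deliberately written from the definitions, without
reusing the package's indexed/vectorised code paths, so agreement is a
two-route check and not a tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    n, k = r1 + r2, a + c
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    obs = comb(r1, a) * comb(r2, c)
    tot = 0
    for x in range(max(0, k - r2), min(k, r1) + 1):
        w = comb(r1, x) * comb(r2, k - x)
        if w <= obs:
            tot += w
    return float(Fraction(tot, comb(n, k)))


def bh_oracle(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: for the i-th smallest p,
    p_adj = min over j >= i of m * p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, m + 1)
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(1.0, (m * sorted_p[i:] / ranks[i:]).min())
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def naive_junction_counts(reads, genes, ir_events, es_events, min_overhang=6):
    """All-pairs junction counter over Read objects.

    Tests every read against every event directly from the event tables.
    Returns (ir, es, gene) dicts: ir[(event_id, sample)] = {EE, EI5, EI3},
    es[...] = {INC1, INC2, SKP}, gene[(gene_id, sample)] = n.
    """
    ir = {}
    es = {}
    gene = {}

    def bump(store, key, cell):
        d = store.setdefault(key, {})
        d[cell] = d.get(cell, 0) + 1

    ir_rows = list(ir_events.itertuples(index=False))
    es_rows = list(es_events.itertuples(index=False))
    gene_spans = [(g.gene_id, g.chrom, g.start, g.end) for g in genes]

    for read in reads:
        gaps = read.gaps
        blocks = read.blocks
        for ev in ir_rows:
            if ev.chrom != read.chrom:
                continue
            # EE: a gap equal to the intron with enough anchor both sides
            for gi, (gs, ge) in enumerate(gaps):
                left = blocks[gi][1] - blocks[gi][0]
                right = blocks[gi + 1][1] - blocks[gi + 1][0]
                if (
                    (gs, ge) == (ev.start, ev.end)
                    and left >= min_overhang
                    and right >= min_overhang
                ):
                    bump(ir, (ev.event_id, read.sample), "EE")
            # EI: a block covering a boundary with enough bases each side
            five, three = (
                (ev.start, ev.end) if ev.strand == "+" else (ev.end, ev.start)
            )
            for (bs, be) in blocks:
                if bs + min_overhang <= five <= be - min_overhang:
                    bump(ir, (ev.event_id, read.sample), "EI5")
                if bs + min_overhang <= three <= be - min_overhang:
                    bump(ir, (ev.event_id, read.sample), "EI3")
        for ev in es_rows:
            if ev.chrom != read.chrom:
                continue
            targets = (
                ("INC1", ev.inc1_start, ev.inc1_end),
                ("INC2", ev.inc2_start, ev.inc2_end),
                ("SKP", ev.skip_start, ev.skip_end),
            )
            for gi, (gs, ge) in enumerate(gaps):
                left = blocks[gi][1] - blocks[gi][0]
                right = blocks[gi + 1][1] - blocks[gi + 1][0]
                if left < min_overhang or right < min_overhang:
                    continue
                for cell, ts, te in targets:
                    if (gs, ge) == (ts, te):
                        bump(es, (ev.event_id, read.sample), cell)
        start = blocks[0][0]
        for gid, chrom, gs, ge in gene_spans:
            if chrom == read.chrom and gs <= start < ge:
                gene[(gid, read.sample)] = gene.get((gid, read.sample), 0) + 1
    return ir, es, gene


def counts_to_dicts(counts):
    """Flatten a JunctionCounts object into the oracle's dict shape,
    dropping all-zero entries."""
    ir = {}
    for t in counts.ir.itertuples(index=False):
        d = {
            c: v
            for c, v in (("EE", t.EE), ("EI5", t.EI5), ("EI3", t.EI3))
            if v
        }
        if d:
            ir[(t.event_id, t.sample)] = d
    es = {}
    for t in counts.es.itertuples(index=False):
        d = {
            c: v
            for c, v in (("INC1", t.INC1), ("INC2", t.INC2), ("SKP", t.SKP))
            if v
        }
        if d:
            es[(t.event_id, t.sample)] = d
    gene = {}
    stacked = counts.gene.stack()
    for (gid, sample), v in stacked.items():
        if v:
            gene[(gid, sample)] = int(v)
    return ir, es, gene


def nb_matrix(rng, mu, dispersion, n_samples):
    """Draw a genes x samples NB count matrix (var = mu + a*mu^2)."""
    mu = np.asarray(mu, dtype=float)
    cols = []
    for _ in range(n_samples):
        if dispersion > 0:
            n = 1.0 / dispersion
            cols.append(rng.negative_binomial(n, n / (n + mu)))
        else:
            cols.append(rng.poisson(mu))
    return np.column_stack(cols)
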