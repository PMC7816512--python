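"""Synthetic two-condition spliced RNA-seq with known ground truth.

The generator emulates the statistical structure of a fission-yeast style
experiment: a compact genome of single-transcript, non-overlapping genes
with short introns; two conditions with replicated, single-end 1x100
libraries; negative-binomial gene-level fragment counts; per-intron
retention fractions and per-internal-exon inclusion fractions that may
differ between conditions; and per-sample library-size factors.

Reads are emitted pre-aligned (blocks + splice gaps, convertible to SAM
with ``N`` CIGAR operations): alignment is not part of the pipeline, so
the simulator produces what an aligner would.

Sampling model
--------------
For each gene and sample, the fragment count is NB with mean
``mu_gene * 2**log2fc * size_factor`` and variance ``m + alpha * m**2``.
Each fragment comes from one isoform "pattern" (a joint assignment of
retained/spliced to every intron and included/skipped to every internal
exon); patterns are drawn with probability proportional to
``prior(pattern) * molecule_length(pattern)``.  The length weighting
mirrors fragmentation of real libraries (longer molecules yield more
fragments) and makes the junction-based PIR/PSI estimators consistent:
boundary and junction windows of one intron then receive reads in exact
proportion ``2*rho : (1 - rho)``.  Read starts are uniform along the
molecule.  A skipped exon removes its flanking introns with it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Exon, Gene
from .counting import DEFAULT_MIN_OVERHANG
from .reads import ReadTable

__all__ = [
    "SimConfig",
    "TruthTable",
    "generate_annotation",
    "make_truth",
    "simulate_reads",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults model a small fission-yeast-like experiment: few short
    introns per gene, highly reproducible replicate cultures (low NB
    dispersion), mostly-spliced introns and mostly-included exons at
    baseline, and mild library-size variation.
    """

    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 4)        # inclusive range
    exon_length: tuple[int, int] = (150, 400)       # bases, inclusive
    intron_length: tuple[int, int] = (40, 120)      # bases, inclusive
    n_replicates: int = 3                           # per condition
    mean_expression: float = 200.0                  # expected fragments/gene
    expression_sdlog: float = 0.5                   # between-gene lognormal spread
    dispersion: float = 0.02                        # NB: var = m + alpha m^2
    retention: tuple[float, float] = (0.10, 0.10)   # default rho per condition
    inclusion: tuple[float, float] = (0.90, 0.90)   # default iota per condition
    library_size_factors: tuple[float, ...] | None = None  # len = 2*n_replicates
    library_size_sdlog: float = 0.15                # used when factors not given
    read_length: int = 100
    seed: int = 0
    conditions: tuple[str, str] = ("c1", "c2")
    chrom_name: str = "sim_1"
    spacer: int = 200                               # intergenic bases

    def __post_init__(self) -> None:
        for name in ("retention", "inclusion"):
            for v in getattr(self, name):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} fractions must lie in [0, 1]")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need at least 2 exons to carry an intron")
        if self.exon_length[0] < self.read_length:
            raise ValueError(
                "minimum exon length must be >= read_length so junction-"
                "spanning reads fit inside flanking exons"
            )
        if self.intron_length[0] < 1:
            raise ValueError("introns must be at least 1 base")
        if self.n_replicates < 1 or self.n_genes < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != 2 * self.n_replicates:
                raise ValueError("need one size factor per sample")
            if any(f <= 0 for f in self.library_size_factors):
                raise ValueError("size factors must be positive")

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_r{i + 1}"
            for cond in self.conditions
            for i in range(self.n_replicates)
        ]


@dataclass
class TruthTable:
    """Simulator ground truth, the oracle for recovery tests.

    ``introns``:  event_id, gene_id, index, length, ret1, ret2,
    delta_pir_true (= 100*(ret2 - ret1)).
    ``exons``:    event_id, gene_id, index, inc1, inc2, delta_psi_true.
    ``genes``:    gene_id, mu, log2fc_true, spliced_length.
    """

    introns: pd.DataFrame
    exons: pd.DataFrame
    genes: pd.DataFrame


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def generate_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], list[Gene]]:
    """Generate a toy genome and gene models; byte-deterministic per seed."""
    rng = _rng(config, 0)
    genes: list[Gene] = []
    pos = config.spacer
    chrom = config.chrom_name
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for ei in range(n_ex):
            if ei:
                pos += int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
            length = int(
                rng.integers(config.exon_length[0], config.exon_length[1] + 1)
            )
            exons.append(Exon(chrom, pos, pos + length, strand))
            pos = exons[-1].end
        genes.append(Gene(f"g{gi + 1:04d}", chrom, strand, tuple(exons)))
        pos += config.spacer
    seq = _BASES[rng.integers(0, 4, size=pos)].tobytes().decode()
    return {chrom: seq}, genes


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            s = genome[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def mean_fragments_for_junction_depth(
    gene: Gene,
    depth_per_condition: float,
    config: SimConfig,
    mean_retention: float,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> float:
    """Per-sample fragment mean giving ~``depth_per_condition`` pooled
    junction-informative reads per intron per condition.

    Junction windows hold ``w = read_length - 2*min_overhang + 1`` start
    positions each; a retained molecule exposes two boundary windows, a
    spliced one exposes one junction window, so the expected number of
    informative reads per fragment is ``w * (1 + rho) / E[molecule length]``.
    """
    w = config.read_length - 2 * min_overhang + 1
    exp_len = gene.spliced_length + mean_retention * sum(
        len(i) for i in gene.introns
    )
    per_sample = depth_per_condition / config.n_replicates
    return per_sample * exp_len / (w * (1.0 + mean_retention))


def make_truth(
    genes: list[Gene],
    config: SimConfig,
    *,
    retention: pd.DataFrame | None = None,
    inclusion: pd.DataFrame | None = None,
    log2fc: dict[str, float] | None = None,
    junction_depth: float | None = None,
) -> TruthTable:
    """Build the ground-truth table the simulator will realise.

    Parameters
    ----------
    retention, inclusion : optional DataFrames indexed by event_id with
        columns ``ret1``/``ret2`` (``inc1``/``inc2``) overriding the
        config-wide default fractions for listed events.
    log2fc : optional per-gene true expression log2 fold change
        (condition 2 vs condition 1); unlisted genes get 0.
    junction_depth : if given, per-gene expression is set so every intron
        collects ~this many pooled junction-informative reads per
        condition (overrides the lognormal expression model).
    """
    rng = _rng(config, 1)
    i_rows, e_rows, g_rows = [], [], []
    for g in genes:
        lfc = (log2fc or {}).get(g.gene_id, 0.0)
        rets = []
        for intr in g.introns:
            eid = f"{g.gene_id}.I{intr.index}"
            r1, r2 = config.retention
            if retention is not None and eid in retention.index:
                r1 = float(retention.loc[eid, "ret1"])
                r2 = float(retention.loc[eid, "ret2"])
            rets.append((r1 + r2) / 2)
            i_rows.append(
                dict(
                    event_id=eid,
                    gene_id=g.gene_id,
                    index=intr.index,
                    length=len(intr),
                    ret1=r1,
                    ret2=r2,
                    delta_pir_true=100.0 * (r2 - r1),
                )
            )
        for i in range(1, len(g.exons) - 1):
            eid = f"{g.gene_id}.E{i}"
            c1, c2 = config.inclusion
            if inclusion is not None and eid in inclusion.index:
                c1 = float(inclusion.loc[eid, "inc1"])
                c2 = float(inclusion.loc[eid, "inc2"])
            e_rows.append(
                dict(
                    event_id=eid,
                    gene_id=g.gene_id,
                    index=i,
                    inc1=c1,
                    inc2=c2,
                    delta_psi_true=100.0 * (c2 - c1),
                )
            )
        if junction_depth is not None:
            mean_ret = float(np.mean(rets)) if rets else 0.0
            mu = mean_fragments_for_junction_depth(
                g, junction_depth, config, mean_ret
            )
        else:
            mu = config.mean_expression * math.exp(
                rng.normal(0.0, config.expression_sdlog)
                - config.expression_sdlog**2 / 2.0
            )
        g_rows.append(
            dict(
                gene_id=g.gene_id,
                mu=mu,
                log2fc_true=lfc,
                spliced_length=g.spliced_length,
            )
        )
    return TruthTable(
        introns=pd.DataFrame(
            i_rows,
            columns=[
                "event_id", "gene_id", "index", "length", "ret1", "ret2",
                "delta_pir_true",
            ],
        ),
        exons=pd.DataFrame(
            e_rows,
            columns=["event_id", "gene_id", "index", "inc1", "inc2",
                     "delta_psi_true"],
        ),
        genes=pd.DataFrame(
            g_rows, columns=["gene_id", "mu", "log2fc_true", "spliced_length"]
        ),
    )


class _GenePatterns:
    """Isoform patterns of one gene: genomic runs and molecule lengths.

    A pattern fixes inclusion of each internal exon and retention of each
    intron whose two neighbouring exons are both included and adjacent.
    Introns flanking a skipped exon leave with it, so their retention
    bits do not enumerate separate patterns.
    """

    __slots__ = ("run_gstart", "run_glen", "run_cum", "length",
                 "pattern_states", "internal", "last_exon")

    def __init__(self, gene: Gene):
        n_ex = len(gene.exons)
        self.internal = list(range(1, n_ex - 1))
        self.last_exon = n_ex - 1
        exon_bounds = [(e.start, e.end) for e in gene.exons]
        self.run_gstart: list[np.ndarray] = []
        self.run_glen: list[np.ndarray] = []
        self.run_cum: list[np.ndarray] = []
        self.length: list[int] = []
        # (inclusion bits over internal exons, retained intron ids) per pattern
        self.pattern_states: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
        for inc_bits in itertools.product([1, 0], repeat=len(self.internal)):
            included = sorted(
                {0, n_ex - 1}
                | {self.internal[i] for i, b in enumerate(inc_bits) if b}
            )
            # intron a sits between exons a and a+1; it is "active" (can be
            # retained) only when both neighbours are included
            active = [a for a, b in zip(included, included[1:]) if b == a + 1]
            for ret_bits in itertools.product([1, 0], repeat=len(active)):
                retained = {a for a, b in zip(active, ret_bits) if b}
                runs: list[list[int]] = []
                for k, ex_i in enumerate(included):
                    s, e = exon_bounds[ex_i]
                    if (
                        runs
                        and k > 0
                        and included[k - 1] == ex_i - 1
                        and (ex_i - 1) in retained
                    ):
                        runs[-1][1] = e  # merge across retained intron
                    else:
                        runs.append([s, e])
                glen = np.array([r[1] - r[0] for r in runs], dtype=np.int64)
                self.run_gstart.append(
                    np.array([r[0] for r in runs], dtype=np.int64)
                )
                self.run_glen.append(glen)
                self.run_cum.append(np.concatenate([[0], np.cumsum(glen)]))
                self.length.append(int(glen.sum()))
                self.pattern_states.append((inc_bits, tuple(sorted(retained))))


def simulate_reads(
    config: SimConfig,
    genes: list[Gene],
    truth: TruthTable,
) -> tuple[ReadTable, pd.DataFrame]:
    """Simulate per-sample aligned single-end reads.

    Returns the read table and the design frame (sample, condition,
    size_factor).  Deterministic for a given config seed.
    """
    rng = _rng(config, 2)
    samples = config.samples
    n_rep = config.n_replicates
    if config.library_size_factors is not None:
        sfs = np.asarray(config.library_size_factors, dtype=float)
    else:
        sd = config.library_size_sdlog
        sfs = np.exp(rng.normal(0.0, sd, size=len(samples)) - sd**2 / 2.0)
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": [c for c in config.conditions for _ in range(n_rep)],
            "size_factor": sfs,
        }
    )

    intr_truth = truth.introns.set_index(["gene_id", "index"])
    exon_truth = truth.exons.set_index(["gene_id", "index"])
    gene_truth = truth.genes.set_index("gene_id")

    rl = config.read_length
    alpha = config.dispersion
    chrom_code = 0  # single chromosome

    out_sc, out_b1s, out_b1l, out_b2s, out_b2l = [], [], [], [], []

    for g in genes:
        gp = _GenePatterns(g)
        rhos_by_cond = []
        iota_by_cond = []
        for cond_i in (0, 1):
            col_r = "ret1" if cond_i == 0 else "ret2"
            col_c = "inc1" if cond_i == 0 else "inc2"
            rhos = [
                float(intr_truth.loc[(g.gene_id, i), col_r])
                for i in range(len(g.exons) - 1)
            ]
            if len(g.exons) > 2:
                iotas = [
                    float(exon_truth.loc[(g.gene_id, i), col_c])
                    for i in range(1, len(g.exons) - 1)
                ]
            else:
                iotas = []
            rhos_by_cond.append(rhos)
            iota_by_cond.append(iotas)
        mu0 = float(gene_truth.loc[g.gene_id, "mu"])
        lfc = float(gene_truth.loc[g.gene_id, "log2fc_true"])
        weights_by_cond = [
            _pattern_weights(gp, iota_by_cond[c], rhos_by_cond[c])
            for c in (0, 1)
        ]
        for si, sample in enumerate(samples):
            cond_i = 0 if si < n_rep else 1
            mean = mu0 * (2.0**lfc if cond_i == 1 else 1.0) * sfs[si]
            if mean <= 0:
                continue
            if alpha > 0:
                n_param = 1.0 / alpha
                p_param = n_param / (n_param + mean)
                n_frag = int(rng.negative_binomial(n_param, p_param))
            else:
                n_frag = int(rng.poisson(mean))
            if n_frag == 0:
                continue
            pat_counts = rng.multinomial(n_frag, weights_by_cond[cond_i])
            for k in np.nonzero(pat_counts)[0]:
                cnt = int(pat_counts[k])
                L = gp.length[k]
                if L < rl:
                    continue  # molecule too short to host a read
                starts = rng.integers(0, L - rl + 1, size=cnt)
                cum = gp.run_cum[k]
                gstart = gp.run_gstart[k]
                glen = gp.run_glen[k]
                run_i = np.searchsorted(cum, starts, side="right") - 1
                off = starts - cum[run_i]
                len1 = np.minimum(rl, glen[run_i] - off)
                b1s = gstart[run_i] + off
                len2 = rl - len1
                nxt = np.minimum(run_i + 1, len(gstart) - 1)
                b2s = np.where(len2 > 0, gstart[nxt], 0)
                out_sc.append(np.full(cnt, si, dtype=np.int64))
                out_b1s.append(b1s.astype(np.int64))
                out_b1l.append(len1.astype(np.int64))
                out_b2s.append(b2s.astype(np.int64))
                out_b2l.append(len2.astype(np.int64))

    if out_sc:
        sc = np.concatenate(out_sc)
        b1s = np.concatenate(out_b1s)
        b1l = np.concatenate(out_b1l)
        b2s = np.concatenate(out_b2s)
        b2l = np.concatenate(out_b2l)
    else:
        sc = b1s = b1l = b2s = b2l = np.zeros(0, dtype=np.int64)
    cc = np.full(len(sc), chrom_code, dtype=np.int64)
    rt = ReadTable.from_blocks(
        samples, [config.chrom_name], sc, cc, b1s, b1l, b2s, b2l
    )
    return rt, design


def _pattern_weights(gp: _GenePatterns, iotas: list[float],
                     rhos: list[float]) -> np.ndarray:
    """Length-weighted pattern probabilities with per-exon inclusion."""
    w = np.empty(len(gp.length))
    last_exon = gp.last_exon
    for k, (inc_bits, retained) in enumerate(gp.pattern_states):
        p = 1.0
        for j, b in enumerate(inc_bits):
            p *= iotas[j] if b else (1.0 - iotas[j])
        included = sorted(
            {0, last_exon}
            | {gp.internal[i] for i, b in enumerate(inc_bits) if b}
        )
        active = [a for a, b in zip(included, included[1:]) if b == a + 1]
        ret_set = set(retained)
        for a in active:
            p *= rhos[a] if a in ret_set else (1.0 - rhos[a])
        w[k] = p * gp.length[k]
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate pattern weights")
    return w / total
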