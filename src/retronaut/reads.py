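"""Aligned-read container.

Reads are stored in a columnar :class:`ReadTable` — three flat pandas
frames (one row per read, per aligned block, per splice gap) — so the
junction counter can work on whole arrays at once.  The table is built
either by the simulator or from SAM files (CIGAR ``N`` operations become
splice gaps).  Strand is deliberately not tracked: the library protocol
this models (random-hexamer primed, single-end) is unstranded.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam

__all__ = ["Read", "ReadTable"]

# CIGAR operation codes (pysam convention)
_C_M, _C_I, _C_D, _C_N, _C_S, _C_EQ, _C_X = 0, 1, 2, 3, 4, 7, 8
_REF_CONSUMING = {_C_M, _C_D, _C_EQ, _C_X}


class Read(NamedTuple):
    """A single alignment: ordered, non-overlapping blocks on one chrom."""

    sample: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        )


@dataclass
class ReadTable:
    """Columnar set of aligned reads across samples.

    Attributes
    ----------
    samples, chroms : list[str]
        Code tables; integer columns below index into them.
    reads : DataFrame with columns [sample, chrom, start]
        One row per read; ``start`` is the leftmost aligned base.
    blocks : DataFrame with columns [read, sample, chrom, start, end]
        One row per aligned block.
    gaps : DataFrame with columns [read, sample, chrom, start, end, left, right]
        One row per splice gap; ``left``/``right`` are the lengths of the
        flanking aligned blocks (the junction overhangs).
    """

    samples: list[str]
    chroms: list[str]
    reads: pd.DataFrame
    blocks: pd.DataFrame
    gaps: pd.DataFrame

    def __len__(self) -> int:
        return len(self.reads)

    @classmethod
    def from_blocks(
        cls,
        samples: list[str],
        chroms: list[str],
        sample_code: np.ndarray,
        chrom_code: np.ndarray,
        b1_start: np.ndarray,
        b1_len: np.ndarray,
        b2_start: np.ndarray,
        b2_len: np.ndarray,
    ) -> "ReadTable":
        """Build from at-most-two-block reads (the simulator's output).

        ``b2_len == 0`` marks a contiguous read.
        """
        n = len(b1_start)
        read_id = np.arange(n, dtype=np.int64)
        reads = pd.DataFrame(
            {"sample": sample_code, "chrom": chrom_code, "start": b1_start}
        )
        spliced = b2_len > 0
        blocks = pd.DataFrame(
            {
                "read": np.concatenate([read_id, read_id[spliced]]),
                "sample": np.concatenate([sample_code, sample_code[spliced]]),
                "chrom": np.concatenate([chrom_code, chrom_code[spliced]]),
                "start": np.concatenate([b1_start, b2_start[spliced]]),
                "end": np.concatenate(
                    [b1_start + b1_len, b2_start[spliced] + b2_len[spliced]]
                ),
            }
        )
        gaps = pd.DataFrame(
            {
                "read": read_id[spliced],
                "sample": sample_code[spliced],
                "chrom": chrom_code[spliced],
                "start": (b1_start + b1_len)[spliced],
                "end": b2_start[spliced],
                "left": b1_len[spliced],
                "right": b2_len[spliced],
            }
        )
        return cls(list(samples), list(chroms), reads, blocks, gaps)

    @classmethod
    def from_reads(cls, reads: list[Read]) -> "ReadTable":
        """Build from :class:`Read` objects (arbitrary block counts)."""
        samples = sorted({r.sample for r in reads})
        chroms = sorted({r.chrom for r in reads})
        s_idx = {s: i for i, s in enumerate(samples)}
        c_idx = {c: i for i, c in enumerate(chroms)}
        r_rows, b_rows, g_rows = [], [], []
        for i, r in enumerate(reads):
            sc, cc = s_idx[r.sample], c_idx[r.chrom]
            r_rows.append((sc, cc, r.blocks[0][0]))
            for s, e in r.blocks:
                b_rows.append((i, sc, cc, s, e))
            for (a, b), (ls, le), (rs, re) in zip(
                r.gaps, r.blocks, r.blocks[1:]
            ):
                g_rows.append((i, sc, cc, a, b, le - ls, re - rs))
        reads_df = pd.DataFrame(r_rows, columns=["sample", "chrom", "start"])
        blocks_df = pd.DataFrame(
            b_rows, columns=["read", "sample", "chrom", "start", "end"]
        )
        gaps_df = pd.DataFrame(
            g_rows,
            columns=["read", "sample", "chrom", "start", "end", "left", "right"],
        )
        return cls(samples, chroms, reads_df, blocks_df, gaps_df)

    @classmethod
    def from_sam(cls, paths: dict[str, str | os.PathLike]) -> "ReadTable":
        """Read one SAM file per sample (``{sample_id: path}``)."""
        reads: list[Read] = []
        for sample in sorted(paths):
            with pysam.AlignmentFile(str(paths[sample]), "r", check_sq=False) as fh:
                for aln in fh:
                    if aln.is_unmapped or aln.cigartuples is None:
                        continue
                    blocks: list[tuple[int, int]] = []
                    pos = aln.reference_start
                    cur = pos
                    for op, length in aln.cigartuples:
                        if op == _C_N:
                            if pos > cur:
                                blocks.append((cur, pos))
                            pos += length
                            cur = pos
                        elif op in _REF_CONSUMING:
                            pos += length
                    if pos > cur:
                        blocks.append((cur, pos))
                    if blocks:
                        reads.append(
                            Read(sample, aln.reference_name, tuple(blocks))
                        )
        return cls.from_reads(reads)

    def iter_reads(self) -> Iterator[Read]:
        """Yield reads as objects (small-data / oracle use)."""
        blk = self.blocks.sort_values(["read", "start"], kind="stable")
        grouped = blk.groupby("read", sort=True)
        for rid, grp in grouped:
            row = self.reads.iloc[int(rid)]
            yield Read(
                self.samples[int(row["sample"])],
                self.chroms[int(row["chrom"])],
                tuple(zip(grp["start"].tolist(), grp["end"].tolist())),
            )

    def to_sam(self, genome: dict[str, str], outdir: str | os.PathLike,
               template: str = "{sample}.sam") -> dict[str, str]:
        """Write one SAM file per sample; returns ``{sample: path}``.

        Sequences are sliced from ``genome``; qualities are a constant
        placeholder.  The header carries only HD/SQ lines so output is
        byte-stable across runs.
        """
        os.makedirs(outdir, exist_ok=True)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in self.chroms],
        }
        paths: dict[str, str] = {}
        blk = self.blocks.sort_values(["read", "start"], kind="stable")
        starts = blk["start"].to_numpy()
        ends = blk["end"].to_numpy()
        rids = blk["read"].to_numpy()
        order = np.argsort(rids, kind="stable")
        starts, ends, rids = starts[order], ends[order], rids[order]
        bounds = np.searchsorted(rids, np.arange(len(self.reads) + 1))
        sample_of = self.reads["sample"].to_numpy()
        chrom_of = self.reads["chrom"].to_numpy()
        handles = {}
        for si, sample in enumerate(self.samples):
            path = os.path.join(str(outdir), template.format(sample=sample))
            paths[sample] = path
            handles[si] = pysam.AlignmentFile(path, "wh", header=header)
        try:
            for rid in range(len(self.reads)):
                lo, hi = bounds[rid], bounds[rid + 1]
                bs, be = starts[lo:hi], ends[lo:hi]
                cname = self.chroms[int(chrom_of[rid])]
                seq = "".join(
                    genome[cname][s:e] for s, e in zip(bs, be)
                )
                cig = []
                for k in range(len(bs)):
                    if k:
                        cig.append((_C_N, int(bs[k] - be[k - 1])))
                    cig.append((_C_M, int(be[k] - bs[k])))
                a = pysam.AlignedSegment()
                a.query_name = f"r{rid}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = int(chrom_of[rid])
                a.reference_start = int(bs[0])
                a.mapping_quality = 60
                a.cigartuples = cig
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                handles[int(sample_of[rid])].write(a)
        finally:
            for h in handles.values():
                h.close()
        return paths
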