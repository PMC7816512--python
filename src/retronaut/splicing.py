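"""PIR/PSI differential-splicing statistics.

For an intron-retention event the retained evidence is the two
exon-intron boundary counts, the spliced evidence the exon-exon junction
count; the EE count is doubled so one spliced junction balances the two
measurable retained boundaries:

    PIR = 100 * (EI5 + EI3) / (EI5 + EI3 + 2*EE)

Exon skipping is symmetric with inclusion/skipping junctions:

    PSI = 100 * (INC1 + INC2) / (INC1 + INC2 + 2*SKP)

Replicates are pooled (summed) per condition; each event is tested with
a two-sided Fisher's exact test on the 2x2 table
[[retained_1, spliced_1], [retained_2, spliced_2]] and the family of
testable events of one type is BH-adjusted.  An event is testable when
its pooled retained+spliced evidence reaches ``min_reads`` in *each*
condition (the "expressed" filter); untestable events are classified
``not_expressed`` and do not enter the adjustment family.

Classification (the dual threshold): ``increased`` iff adjusted p <
``alpha`` and delta > +``delta_min`` percentage points; ``decreased``
iff adjusted p < ``alpha`` and delta < -``delta_min``; else
``not_significant``.  Delta is condition2 minus condition1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_pir",
    "compute_psi",
    "fisher_event",
    "bh_adjust",
    "classify_events",
    "test_splicing",
]

DEFAULT_ALPHA = 0.05
DEFAULT_DELTA_MIN = 10.0
DEFAULT_MIN_READS = 10

INCREASED = "increased"
DECREASED = "decreased"
NOT_SIGNIFICANT = "not_significant"
NOT_EXPRESSED = "not_expressed"


def _ratio_pct(retained, spliced):
    retained = np.asarray(retained, dtype=float)
    spliced = np.asarray(spliced, dtype=float)
    denom = retained + spliced
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * retained / denom
    return np.where(denom > 0, out, np.nan)


def compute_pir(ei5, ei3, ee):
    """Percent Intron Retained from boundary and junction counts.

    Returns NaN where all three counts are zero (no evidence).
    Accepts scalars or arrays.
    """
    res = _ratio_pct(np.asarray(ei5) + np.asarray(ei3), 2.0 * np.asarray(ee))
    return float(res) if np.isscalar(ei5) else res


def compute_psi(inc1, inc2, skp):
    """Percent Spliced In from inclusion and skipping junction counts."""
    res = _ratio_pct(np.asarray(inc1) + np.asarray(inc2), 2.0 * np.asarray(skp))
    return float(res) if np.isscalar(inc1) else res


def fisher_event(r1: int, s1: int, r2: int, s2: int) -> float:
    """Two-sided Fisher's exact p for the table [[r1, s1], [r2, s2]].

    Uses the minimum-likelihood convention: the sum of hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (ties detected with
    a small relative tolerance against rounding).  A zero row or column
    margin carries no evidence and yields p = 1.
    """
    r1, s1, r2, s2 = int(r1), int(s1), int(r2), int(s2)
    if min(r1, s1, r2, s2) < 0:
        raise ValueError("counts must be non-negative")
    row1, row2 = r1 + s1, r2 + s2
    n, k = row1 + row2, r1 + r2
    if row1 == 0 or row2 == 0 or k == 0 or k == n:
        return 1.0
    x = np.arange(max(0, k - row2), min(k, row1) + 1)
    logpmf = (
        gammaln(row1 + 1) - gammaln(x + 1) - gammaln(row1 - x + 1)
        + gammaln(row2 + 1) - gammaln(k - x + 1) - gammaln(row2 - k + x + 1)
        - (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    )
    pmf = np.exp(logpmf)
    obs = pmf[x == r1][0]
    return float(min(1.0, pmf[pmf <= obs * (1.0 + 1e-7)].sum()))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_events(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                    delta_min: float = DEFAULT_DELTA_MIN) -> pd.DataFrame:
    """Apply the dual significance threshold to a results frame.

    Requires ``p_adj`` and ``delta`` columns; rows with NaN ``p_adj``
    (not tested) are classified ``not_expressed``.
    """
    out = results.copy()
    p_adj = out["p_adj"].to_numpy(dtype=float)
    delta = out["delta"].to_numpy(dtype=float)
    cls = np.full(len(out), NOT_SIGNIFICANT, dtype=object)
    sig = p_adj < alpha
    cls[sig & (delta > delta_min)] = INCREASED
    cls[sig & (delta < -delta_min)] = DECREASED
    cls[np.isnan(p_adj)] = NOT_EXPRESSED
    out["classification"] = cls
    return out


def _pool(counts: pd.DataFrame, design: pd.DataFrame,
          contrast: tuple[str, str], cols: list[str]) -> pd.DataFrame:
    cond_of = dict(zip(design["sample"], design["condition"]))
    df = counts.copy()
    df["condition"] = df["sample"].map(cond_of)
    missing = df["condition"].isna()
    if missing.any():
        raise ValueError(
            f"samples missing from design: {sorted(df.loc[missing, 'sample'].unique())}"
        )
    pooled = (
        df[df["condition"].isin(contrast)]
        .groupby(["event_id", "condition"], sort=False)[cols]
        .sum()
        .unstack("condition")
    )
    return pooled


def test_splicing(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    event_type: str = "IR",
    contrast: tuple[str, str] | None = None,
    events: pd.DataFrame | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    delta_min: float = DEFAULT_DELTA_MIN,
) -> pd.DataFrame:
    """Per-event differential splicing for one event type.

    Parameters
    ----------
    counts : tidy count frame from the counter — columns
        [event_id, sample, EE, EI5, EI3] (IR) or
        [event_id, sample, INC1, INC2, SKP] (ES).
    design : frame with ``sample`` and ``condition`` columns.
    event_type : "IR" or "ES".
    contrast : (reference condition, test condition); delta is test minus
        reference.  Defaults to the two conditions in design order.
    events : optional event table supplying ``gene_id`` per event.

    Returns a frame with one row per event: pooled counts, the PIR/PSI
    level per condition, delta, mean_log2_count (MA x-axis: log2 of 1 +
    the across-sample mean of total event reads), Fisher p, BH-adjusted
    p, and the classification.  ``df.attrs["statistic"]`` records whether
    levels are PIR or PSI.
    """
    if event_type == "IR":
        part_cols, junction_col, stat_name = ["EI5", "EI3"], "EE", "PIR"
    elif event_type == "ES":
        part_cols, junction_col, stat_name = ["INC1", "INC2"], "SKP", "PSI"
    else:
        raise ValueError("event_type must be 'IR' or 'ES'")
    if contrast is None:
        conds = list(dict.fromkeys(design["condition"]))
        if len(conds) != 2:
            raise ValueError("design must have exactly two conditions")
        contrast = (conds[0], conds[1])

    all_cols = part_cols + [junction_col]
    pooled = _pool(counts, design, contrast, all_cols)
    c1, c2 = contrast
    retained1 = sum(pooled[(c, c1)] for c in part_cols).astype(np.int64)
    retained2 = sum(pooled[(c, c2)] for c in part_cols).astype(np.int64)
    spliced1 = (2 * pooled[(junction_col, c1)]).astype(np.int64)
    spliced2 = (2 * pooled[(junction_col, c2)]).astype(np.int64)

    total = counts[all_cols].sum(axis=1)
    mean_total = (
        pd.DataFrame({"event_id": counts["event_id"], "t": total})
        .groupby("event_id", sort=False)["t"]
        .mean()
    )

    res = pd.DataFrame(
        {
            "event_id": pooled.index,
            "r1": retained1.to_numpy(),
            "s1": spliced1.to_numpy(),
            "r2": retained2.to_numpy(),
            "s2": spliced2.to_numpy(),
        }
    )
    res["level1"] = _ratio_pct(res["r1"], res["s1"])
    res["level2"] = _ratio_pct(res["r2"], res["s2"])
    res["delta"] = res["level2"] - res["level1"]
    res["mean_log2_count"] = np.log2(
        1.0 + mean_total.reindex(res["event_id"]).to_numpy()
    )

    testable = ((res["r1"] + res["s1"]) >= min_reads) & (
        (res["r2"] + res["s2"]) >= min_reads
    )
    pvals = np.full(len(res), np.nan)
    idx = np.nonzero(testable.to_numpy())[0]
    for i in idx:
        pvals[i] = fisher_event(
            res.at[i, "r1"], res.at[i, "s1"], res.at[i, "r2"], res.at[i, "s2"]
        )
    res["p"] = pvals
    p_adj = np.full(len(res), np.nan)
    if len(idx):
        p_adj[idx] = bh_adjust(pvals[idx])
    res["p_adj"] = p_adj

    res = classify_events(res, alpha=alpha, delta_min=delta_min)
    if events is not None:
        res.insert(
            1,
            "gene_id",
            res["event_id"].map(
                dict(zip(events["event_id"], events["gene_id"]))
            ),
        )
    res = res.rename(
        columns={"level1": f"{stat_name.lower()}1", "level2": f"{stat_name.lower()}2"}
    )
    res = res.sort_values("event_id", kind="stable").reset_index(drop=True)
    res.attrs["statistic"] = stat_name
    res.attrs["contrast"] = contrast
    res.attrs["alpha"] = alpha
    res.attrs["delta_min"] = delta_min
    return res
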