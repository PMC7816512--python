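"""Simplified negative-binomial differential gene expression.

A deliberately small DE stage: median-of-ratios size factors, a single
method-of-moments dispersion shared by all genes, and a conditional NB
test in the style of the classic DESeq exact test — the per-condition
count sums ``K_A`` and ``K_B`` are modelled as NB, and the two-sided p
is the probability, conditional on ``K_A + K_B``, of a split no more
likely than the observed one.  No per-gene dispersion shrinkage, no GLM;
this is not a numerical replica of DESeq, only a calibrated NB test with
the same normalisation scheme.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .splicing import bh_adjust

__all__ = ["size_factors", "common_dispersion", "test_dge"]

DEFAULT_ALPHA = 0.05
_MIN_DISP = 1e-8

UP = "up"
DOWN = "down"
NS = "ns"
EXCLUDED = "excluded"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    ``counts`` is genes x samples.  The reference is the per-gene
    geometric mean over samples, restricted to genes with a nonzero
    count in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios needs at least one such reference gene"
        )
    logs = np.log(mat[all_nonzero])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _split(design: pd.DataFrame, contrast: tuple[str, str],
           samples: list[str]) -> tuple[list[str], list[str]]:
    cond_of = dict(zip(design["sample"], design["condition"]))
    a = [s for s in samples if cond_of.get(s) == contrast[0]]
    b = [s for s in samples if cond_of.get(s) == contrast[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per condition")
    return a, b


def common_dispersion(counts: pd.DataFrame, sf: pd.Series,
                      design: pd.DataFrame,
                      contrast: tuple[str, str]) -> float:
    """Method-of-moments common NB dispersion (var = mu + alpha*mu^2).

    Within each condition, the normalised per-gene sample variance in
    excess of the shot-noise term estimates ``alpha * q^2``; the average
    of the per-gene ratios over both conditions is returned (floored at
    a tiny positive value).
    """
    a, b = _split(design, contrast, list(counts.columns))
    ests = []
    for group in (a, b):
        sub = counts[group].to_numpy(dtype=float)
        s = sf[group].to_numpy(dtype=float)
        z = sub / s  # normalised counts
        q = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        shot = q * np.mean(1.0 / s)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = (v - shot) / q**2
        ests.append(w[q > 0])
    pooled = np.concatenate(ests)
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        return _MIN_DISP
    return float(max(pooled.mean(), _MIN_DISP))


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    size = 1.0 / alpha
    p = size / (size + mean)
    return sps.nbinom.logpmf(k, size, p)


def _exact_nb_p(k_a: int, k_b: int, mu_a: float, mu_b: float,
                alpha_a: float, alpha_b: float) -> float:
    """Two-sided conditional NB test on the split of K = k_a + k_b."""
    k = k_a + k_b
    if k == 0 or mu_a <= 0 or mu_b <= 0:
        return 1.0
    a = np.arange(k + 1)
    logp = _nb_logpmf(a, mu_a, alpha_a) + _nb_logpmf(k - a, mu_b, alpha_b)
    obs = logp[k_a]
    keep = logp <= obs + 1e-8
    return float(min(1.0, np.exp(logsumexp(logp[keep]) - logsumexp(logp))))


def test_dge(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    dispersion: float | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene NB test of equal normalised means between two conditions.

    ``counts`` is the genes x samples matrix from the counter.  Genes
    with zero counts in every sample are excluded from testing (and from
    the BH family) and flagged ``excluded``.  Returns a frame with
    gene_id, base_mean (mean normalised count), log2fc (condition 2 vs
    condition 1, pseudocount on normalised means), p, p_adj and
    direction (up/down/ns/excluded at the adjusted-p threshold).
    """
    if contrast is None:
        conds = list(dict.fromkeys(design["condition"]))
        if len(conds) != 2:
            raise ValueError("design must have exactly two conditions")
        contrast = (conds[0], conds[1])
    a_samp, b_samp = _split(design, contrast, list(counts.columns))

    nonzero = counts.sum(axis=1) > 0
    mat = counts.loc[nonzero]
    sf = size_factors(mat)
    if dispersion is None:
        dispersion = common_dispersion(mat, sf, design, contrast)

    sa = sf[a_samp].to_numpy()
    sb = sf[b_samp].to_numpy()
    A = mat[a_samp].to_numpy(dtype=np.int64)
    B = mat[b_samp].to_numpy(dtype=np.int64)
    k_a = A.sum(axis=1)
    k_b = B.sum(axis=1)
    S_a, S_b = sa.sum(), sb.sum()

    q_hat = (k_a + k_b) / (S_a + S_b)  # pooled normalised mean under H0
    mu_a = q_hat * S_a
    mu_b = q_hat * S_b
    # a sum of per-replicate NB(q*s_r, alpha) has dispersion scaled by
    # sum(s^2)/S^2 at the same total mean
    alpha_a = dispersion * (sa**2).sum() / S_a**2
    alpha_b = dispersion * (sb**2).sum() / S_b**2

    pvals = np.array(
        [
            _exact_nb_p(
                int(k_a[i]), int(k_b[i]), float(mu_a[i]), float(mu_b[i]),
                max(alpha_a, _MIN_DISP), max(alpha_b, _MIN_DISP),
            )
            for i in range(len(mat))
        ]
    )
    p_adj = bh_adjust(pvals)

    qa = k_a / S_a
    qb = k_b / S_b
    log2fc = np.log2((qb + pseudocount) / (qa + pseudocount))
    base_mean = (np.concatenate([A / sa, B / sb], axis=1)).mean(axis=1)

    direction = np.full(len(mat), NS, dtype=object)
    direction[(p_adj < alpha) & (log2fc > 0)] = UP
    direction[(p_adj < alpha) & (log2fc < 0)] = DOWN

    tested = pd.DataFrame(
        {
            "gene_id": mat.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "direction": direction,
        }
    )
    excluded_ids = counts.index[~nonzero]
    excluded = pd.DataFrame(
        {
            "gene_id": excluded_ids,
            "base_mean": 0.0,
            "log2fc": np.nan,
            "p": np.nan,
            "p_adj": np.nan,
            "direction": EXCLUDED,
        }
    )
    res = pd.concat([tested, excluded], ignore_index=True)
    res = res.sort_values("gene_id", kind="stable").reset_index(drop=True)
    res.attrs["contrast"] = contrast
    res.attrs["dispersion"] = float(dispersion)
    res.attrs["alpha"] = alpha
    return res
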