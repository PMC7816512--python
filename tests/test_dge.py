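import numpy as np
import pandas as pd
import pytest

from retronaut.dge import EXCLUDED, common_dispersion, size_factors
from retronaut.dge import test_dge as run_dge

from helpers import nb_matrix


def _design(n=3):
    samples = [f"c1_r{i}" for i in range(1, n + 1)] + [
        f"c2_r{i}" for i in range(1, n + 1)
    ]
    return pd.DataFrame(
        {"sample": samples, "condition": ["c1"] * n + ["c2"] * n}
    ), samples


def test_size_factors_identical_columns_are_one():
    df = pd.DataFrame({"a": [10, 40, 7], "b": [10, 40, 7]}, index=list("xyz"))
    assert size_factors(df).to_numpy() == pytest.approx([1.0, 1.0])


def test_size_factors_scale_with_library_size():
    df = pd.DataFrame({"a": [10, 40], "b": [20, 80]}, index=list("xy"))
    sf = size_factors(df)
    assert sf["b"] / sf["a"] == pytest.approx(2.0)
    # hand median-of-ratios: geomeans (sqrt(200), sqrt(3200))
    assert sf["a"] == pytest.approx(10 / np.sqrt(200))


def test_size_factors_need_an_all_nonzero_gene():
    df = pd.DataFrame({"a": [0, 5], "b": [3, 0]}, index=list("xy"))
    with pytest.raises(ValueError, match="nonzero"):
        size_factors(df)


def test_noise_free_twofold_gene_has_unit_log2fc():
    design, samples = _design()
    base = np.full(50, 1000)
    mat = np.tile(base[:, None], (1, 6))
    mat = np.vstack([mat, [[1000] * 3 + [2000] * 3]])
    df = pd.DataFrame(mat, index=[f"g{i}" for i in range(51)], columns=samples)
    res = run_dge(df, design, dispersion=0.02).set_index("gene_id")
    assert res.loc["g50", "log2fc"] == pytest.approx(1.0, abs=0.01)
    assert abs(res.loc["g0", "log2fc"]) < 0.01


def test_normalisation_absorbs_pure_library_scaling():
    """Scaling one sample by c multiplies its size factor by c and leaves
    fold changes unchanged (noise-free proportional columns)."""
    design, samples = _design()
    rng = np.random.default_rng(4)
    base = rng.integers(50, 500, size=40)
    mat = np.tile(base[:, None], (1, 6)).astype(float)
    mat[:, 5] += base  # condition-2 replicate structure stays proportional
    df1 = pd.DataFrame(mat, index=[f"g{i}" for i in range(40)], columns=samples)
    df2 = df1.copy()
    df2[samples[0]] = df2[samples[0]] * 3
    sf1, sf2 = size_factors(df1), size_factors(df2)
    # factors are defined up to a common constant: relative to another
    # sample, the scaled library's factor grows by exactly c
    rel1 = sf1[samples[0]] / sf1[samples[1]]
    rel2 = sf2[samples[0]] / sf2[samples[1]]
    assert rel2 / rel1 == pytest.approx(3.0)
    r1 = run_dge(df1.round().astype(int), design, dispersion=0.02)
    r2 = run_dge(df2.round().astype(int), design, dispersion=0.02)
    assert r1["log2fc"].to_numpy() == pytest.approx(r2["log2fc"].to_numpy())


def test_all_zero_gene_is_excluded():
    design, samples = _design()
    rng = np.random.default_rng(1)
    mat = nb_matrix(rng, np.full(20, 100.0), 0.02, 6)
    mat[3] = 0
    df = pd.DataFrame(mat, index=[f"g{i}" for i in range(20)], columns=samples)
    res = run_dge(df, design).set_index("gene_id")
    assert res.loc["g3", "direction"] == EXCLUDED
    assert np.isnan(res.loc["g3", "p"])
    # excluded gene is not part of the BH family
    tested = res[res["direction"] != EXCLUDED]
    assert len(tested) == 19


def test_dispersion_estimate_recovers_truth():
    design, samples = _design(4)
    rng = np.random.default_rng(2)
    mu = 200 * np.exp(rng.normal(0, 0.4, size=1500))
    mat = nb_matrix(rng, mu, 0.05, 8)
    df = pd.DataFrame(mat, index=[f"g{i}" for i in range(1500)], columns=samples)
    sf = size_factors(df)
    alpha = common_dispersion(df, sf, design, ("c1", "c2"))
    assert alpha == pytest.approx(0.05, rel=0.25)


def test_null_pvalues_are_roughly_uniform():
    design, samples = _design()
    rng = np.random.default_rng(7)
    mu = 100 * np.exp(rng.normal(0, 0.5, size=400))
    df = pd.DataFrame(
        nb_matrix(rng, mu, 0.02, 6),
        index=[f"g{i}" for i in range(400)],
        columns=samples,
    )
    res = run_dge(df, design)
    assert (res["p"] < 0.05).mean() < 0.09
    assert res["p"].median() > 0.25
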