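import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from retronaut.splicing import (
    DECREASED,
    INCREASED,
    NOT_EXPRESSED,
    NOT_SIGNIFICANT,
    bh_adjust,
    classify_events,
    compute_pir,
    compute_psi,
    fisher_event,
)
from retronaut.splicing import test_splicing as run_splicing

from helpers import bh_oracle, fisher_exact_oracle


@pytest.mark.parametrize(
    "ei5,ei3,ee,expected",
    [(0, 0, 10, 0.0), (10, 10, 0, 100.0), (6, 4, 5, 50.0)],
)
def test_pir_formula(ei5, ei3, ee, expected):
    assert compute_pir(ei5, ei3, ee) == pytest.approx(expected)


@pytest.mark.parametrize(
    "inc1,inc2,skp,expected",
    [(10, 10, 0, 100.0), (0, 0, 7, 0.0), (3, 1, 2, 50.0)],
)
def test_psi_formula(inc1, inc2, skp, expected):
    assert compute_psi(inc1, inc2, skp) == pytest.approx(expected)


def test_pir_undefined_without_evidence():
    assert math.isnan(compute_pir(0, 0, 0))
    assert math.isnan(compute_psi(0, 0, 0))


def test_fisher_reference_values():
    assert fisher_event(5, 5, 5, 5) == 1.0
    # enumeration: only the two extreme tables are as unlikely as observed
    assert fisher_event(10, 0, 0, 10) == pytest.approx(
        2 / math.comb(20, 10), rel=1e-12
    )
    assert fisher_event(0, 0, 8, 3) == 1.0  # zero margin: no evidence
    with pytest.raises(ValueError):
        fisher_event(-1, 2, 3, 4)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    r1=st.integers(0, 30),
    r2=st.integers(0, 30),
    f1=st.floats(0, 1),
    f2=st.floats(0, 1),
)
def test_fisher_matches_enumeration_oracle(r1, r2, f1, f2):
    a = round(f1 * r1)
    c = round(f2 * r2)
    p = fisher_event(a, r1 - a, c, r2 - c)
    assert p == pytest.approx(fisher_exact_oracle(a, r1 - a, c, r2 - c), abs=1e-10)


def test_fisher_agrees_with_scipy_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 120, size=4)
        assert fisher_event(a, b, c, d) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12
        )


def test_bh_reference_values():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04]
    )
    assert len(set(np.round(bh_adjust([0.2, 0.2, 0.2]), 12))) == 1


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
)
def test_bh_matches_stepup_oracle(pvals):
    assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)


def test_bh_adjusted_never_below_raw(rng):
    p = rng.uniform(size=500)
    assert (bh_adjust(p) >= p - 1e-15).all()


@pytest.mark.parametrize(
    "p_adj,delta,expected",
    [
        (0.01, 15.0, INCREASED),
        (0.01, -15.0, DECREASED),
        (0.01, 5.0, NOT_SIGNIFICANT),
        (0.20, 50.0, NOT_SIGNIFICANT),
        (0.01, 10.0, NOT_SIGNIFICANT),  # threshold is strict
        (np.nan, 50.0, NOT_EXPRESSED),
    ],
)
def test_dual_threshold_classification(p_adj, delta, expected):
    df = pd.DataFrame({"p_adj": [p_adj], "delta": [delta]})
    assert classify_events(df)["classification"].iloc[0] == expected


def _counts_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "sample", "EI5", "EI3", "EE"])


def _design():
    return pd.DataFrame(
        {
            "sample": ["c1_r1", "c1_r2", "c2_r1", "c2_r2"],
            "condition": ["c1", "c1", "c2", "c2"],
        }
    )


def test_splicing_pools_replicates_and_signs_delta():
    counts = _counts_frame(
        [
            ("ev", "c1_r1", 1, 1, 9),
            ("ev", "c1_r2", 1, 1, 9),
            ("ev", "c2_r1", 12, 12, 3),
            ("ev", "c2_r2", 12, 12, 3),
        ]
    )
    res = run_splicing(counts, _design(), "IR")
    row = res.iloc[0]
    # pooled: r1 = 4, s1 = 36; r2 = 48, s2 = 12
    assert (row.r1, row.s1, row.r2, row.s2) == (4, 36, 48, 12)
    assert row.pir1 == pytest.approx(10.0)
    assert row.pir2 == pytest.approx(80.0)
    assert row.delta == pytest.approx(70.0)  # condition2 - condition1
    assert row.p == pytest.approx(fisher_exact_oracle(4, 36, 48, 12), abs=1e-12)
    # MA x-axis: log2(1 + mean over the 4 samples of total event reads)
    assert row.mean_log2_count == pytest.approx(np.log2(1 + (11 + 11 + 27 + 27) / 4))
    assert row.classification == INCREASED


def test_expression_filter_excludes_low_count_events_from_family():
    counts = _counts_frame(
        [
            ("lo", "c1_r1", 1, 0, 1), ("lo", "c1_r2", 0, 0, 1),
            ("lo", "c2_r1", 1, 1, 1), ("lo", "c2_r2", 0, 0, 2),
            ("hi", "c1_r1", 5, 5, 40), ("hi", "c1_r2", 5, 5, 40),
            ("hi", "c2_r1", 40, 40, 5), ("hi", "c2_r2", 40, 40, 5),
        ]
    )
    res = run_splicing(counts, _design(), "IR", min_reads=10).set_index("event_id")
    assert res.loc["lo", "classification"] == NOT_EXPRESSED
    assert math.isnan(res.loc["lo", "p_adj"])
    # family has a single member, so p_adj == p for the testable event
    assert res.loc["hi", "p_adj"] == pytest.approx(res.loc["hi", "p"])


def test_zero_count_event_is_not_expressed():
    counts = _counts_frame(
        [(f"z", s, 0, 0, 0) for s in ["c1_r1", "c1_r2", "c2_r1", "c2_r2"]]
    )
    res = run_splicing(counts, _design(), "IR")
    assert res["classification"].iloc[0] == NOT_EXPRESSED
    assert math.isnan(res["pir1"].iloc[0])
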