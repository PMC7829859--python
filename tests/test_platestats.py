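"""Replicate aggregation, responder comparison and reproducibility tests."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hcsquant.platestats import (
    aggregate_replicates,
    call_responder_groups,
    compare_responders,
    dose_response,
    mann_whitney_exact,
)
from hcsquant.platestats import test_reproducibility as chisq_reproducibility

# -------------------------------------------------- replicate aggregation


def test_triplicate_mean_and_sd():
    r = aggregate_replicates([60.0, 62.0, 64.0], "d1", "LPS:dose=1")
    assert r.mean == pytest.approx(62.0)
    assert r.sd == pytest.approx(2.0)  # sample sd, n-1 denominator
    assert r.n_replicates == 3


def test_single_replicate_sd_flagged():
    r = aggregate_replicates([50.0], "d1", "c")
    assert r.mean == 50.0
    assert np.isnan(r.sd)


def test_empty_replicates_rejected():
    with pytest.raises(ValueError):
        aggregate_replicates([], "d1", "c")


@settings(derandomize=True, max_examples=50, deadline=None)
@given(vals=st.lists(st.floats(0, 100), min_size=2, max_size=8), seed=st.integers(0, 100))
def test_aggregation_permutation_invariant(vals, seed):
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(vals))
    a = aggregate_replicates(vals, "d", "c")
    b = aggregate_replicates(shuffled, "d", "c")
    assert a.mean == pytest.approx(b.mean)
    assert a.sd == pytest.approx(b.sd, nan_ok=True)


def test_triplicate_sd_consistent_with_binomial_sampling():
    """Replicate wells drawn from one binomial condition show a spread on the
    scale of the binomial sampling error of the per-well percent."""
    rng = np.random.default_rng(11)
    n_cells, p = 2000, 0.6
    expected_var = (100.0**2) * p * (1 - p) / n_cells  # percent scale
    variances = []
    for _ in range(300):
        percents = 100.0 * rng.binomial(n_cells, p, size=3) / n_cells
        variances.append(aggregate_replicates(percents, "d", "c").sd ** 2)
    assert np.mean(variances) == pytest.approx(expected_var, rel=0.25)


# -------------------------------------------------- dose-response table


def _resp(donor, cond, mean):
    return aggregate_replicates([mean], donor, cond)


def test_dose_table_sorted_with_control():
    rows = [
        _resp("d1", "LPS:dose=100", 80),
        _resp("d1", "none", 5),
        _resp("d1", "LPS:dose=10", 40),
        _resp("d1", "LPS:dose=50", 70),
    ]
    df = dose_response(rows)
    assert list(df["dose"]) == [0.0, 10.0, 50.0, 100.0]
    assert df.attrs["missing_control_donors"] == []


def test_duplicate_dose_rejected():
    rows = [_resp("d1", "LPS:dose=10", 40), _resp("d1", "LPS:dose=10", 42)]
    with pytest.raises(ValueError, match="duplicate dose"):
        dose_response(rows)


def test_missing_control_flagged():
    df = dose_response([_resp("d1", "LPS:dose=10", 40)])
    assert df.attrs["missing_control_donors"] == ["d1"]


# -------------------------------------------------- Mann-Whitney


def pairwise_enumeration_p(x, y):
    """Independent oracle: two-sided exact p by enumerating group assignments,
    scoring U by direct pairwise comparison counts (not ranks)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(group_idx):
        grp = [pooled[i] for i in group_idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(group_idx)]
        return sum((a > b) + 0.5 * (a == b) for a in grp for b in rest)

    mu = n1 * (len(pooled) - n1) / 2
    u_obs = u_of(tuple(range(n1)))
    devs = [abs(u_of(idx) - mu) for idx in combinations(range(len(pooled)), n1)]
    return sum(d >= abs(u_obs - mu) - 1e-9 for d in devs) / len(devs)


def test_all_tied_groups_give_p_one():
    res = compare_responders([50, 50, 50], [50, 50, 50])
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_fully_separated_small_groups():
    u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(2 / 20)  # 2 of the 20 rank assignments as extreme


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_exact_p_matches_scipy_on_tie_free_samples(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=4)
    y = rng.normal(0.8, 1, size=5)
    _, p = mann_whitney_exact(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert p == pytest.approx(float(ref), rel=1e-12)


@pytest.mark.parametrize(
    "x,y",
    [([1, 1, 2], [2, 3, 3]), ([5, 5], [5, 5, 7]), ([1, 2, 2, 3], [2, 4])],
)
def test_exact_p_with_ties_matches_pairwise_enumeration(x, y):
    _, p = mann_whitney_exact(x, y)
    assert p == pytest.approx(pairwise_enumeration_p(x, y), rel=1e-12)


def test_compare_responders_switches_to_asymptotic_for_large_n():
    rng = np.random.default_rng(5)
    low = rng.normal(40, 5, size=8)
    high = rng.normal(85, 5, size=8)
    res = compare_responders(low, high)
    assert res.method == "asymptotic"
    assert res.significant


def test_overlapping_donor_ids_rejected():
    with pytest.raises(ValueError, match="both groups"):
        compare_responders([1, 2], [3, 4], low_ids=["a", "b"], high_ids=["b", "c"])


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        compare_responders([], [1.0])


# -------------------------------------------------- chi-square reproducibility


def test_identical_tables_give_zero_statistic():
    res = chisq_reproducibility((60, 100), (60, 100))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_statistic_matches_direct_formula():
    # observed 2x2: [[60, 40], [30, 70]]
    res = chisq_reproducibility((60, 100), (30, 100))
    obs = np.array([[60, 40], [30, 70]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    direct = ((obs - exp) ** 2 / exp).sum()
    assert res.statistic == pytest.approx(direct, rel=1e-12)
    assert not res.yates_applied


def test_zero_expected_cell_triggers_yates_fallback():
    res = chisq_reproducibility((0, 50), (0, 60))  # nobody activated anywhere
    assert res.yates_applied
    assert res.p_value == pytest.approx(1.0)


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        chisq_reproducibility((5, 3), (1, 10))


# -------------------------------------------------- responder grouping


def test_two_group_split_on_bimodal_means():
    rows = [_resp(d, "c", m) for d, m in [("a", 30), ("b", 35), ("c", 80), ("d", 85)]]
    grp = call_responder_groups(rows)
    assert grp.low == ["a", "b"]
    assert grp.high == ["c", "d"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_split_matches_exhaustive_bipartition_oracle(seed):
    """The contiguous split equals the global within-group-SS minimum over
    every bipartition of the donors."""
    rng = np.random.default_rng(seed)
    means = np.round(rng.uniform(0, 100, size=6), 3)
    rows = [_resp(f"d{i}", "c", m) for i, m in enumerate(means)]
    grp = call_responder_groups(rows)

    def ss(idx):
        a = means[list(idx)]
        b = np.delete(means, list(idx))
        return ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()

    best = min(
        ss(idx)
        for k in range(1, 6)
        for idx in combinations(range(6), k)
    )
    got_low = means[[int(d[1:]) for d in grp.low]]
    got_high = means[[int(d[1:]) for d in grp.high]]
    got_ss = ((got_low - got_low.mean()) ** 2).sum() + ((got_high - got_high.mean()) ** 2).sum()
    assert got_ss == pytest.approx(best, rel=1e-9)


def test_fixed_cutoff_grouping():
    rows = [_resp("a", "c", 30), _resp("b", "c", 90)]
    grp = call_responder_groups(rows, method="fixed_cutoff", cutoff=65)
    assert grp.low == ["a"] and grp.high == ["b"]


def test_identical_means_flagged_single_group():
    rows = [_resp(d, "c", 50.0) for d in "abc"]
    grp = call_responder_groups(rows)
    assert grp.single_group
    assert grp.high == []
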