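"""Replicate aggregation, dose-response tables and responder statistics.

Per-well percent-positive values are aggregated over triplicate wells to a
donor-level mean ± sd. Donors are split into low and high responder groups
either by a fixed percent cutoff or by an exhaustive variance-minimising 1-D
split of their means; the groups are compared with a two-sided Mann-Whitney
U test (exact null by enumeration for small samples, normal approximation
with tie correction otherwise, significance at alpha = 0.05 by default).
Reproducibility between two repeats of an experiment is tested with a
chi-square test on the 2x2 activated / non-activated contingency counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: combined sample size up to which the exact Mann-Whitney null is enumerated
EXACT_MWU_MAX_N = 12


@dataclass
class DonorResponse:
    """Replicate well percents of one donor under one condition."""

    donor_id: str
    condition: str
    replicate_percents: list[float]
    mean: float
    sd: float  # sample sd (n-1); NaN for a single replicate
    n_replicates: int


@dataclass
class ResponderComparison:
    group_low: list[str]
    group_high: list[str]
    u_statistic: float  # U of the low group
    p_value: float
    significant: bool
    alpha: float
    method: str  # "exact" | "asymptotic"


@dataclass
class ReproducibilityTest:
    counts_a: tuple[int, int]  # (n_activated, n_cells)
    counts_b: tuple[int, int]
    statistic: float
    p_value: float
    yates_applied: bool = False


@dataclass
class ResponderGrouping:
    low: list[str]
    high: list[str]
    method: str
    single_group: bool = False
    cutoff: float | None = None


def aggregate_replicates(
    percents: Sequence[float], donor_id: str, condition: str
) -> DonorResponse:
    """Mean and sample sd (n-1 denominator) over replicate well percents."""
    vals = [float(p) for p in percents]
    if not vals:
        raise ValueError("at least one replicate required")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return DonorResponse(
        donor_id=donor_id,
        condition=condition,
        replicate_percents=vals,
        mean=mean,
        sd=sd,
        n_replicates=len(vals),
    )


def dose_response(responses: Sequence[DonorResponse]) -> pd.DataFrame:
    """Ordered dose table per donor, including the 0 (unstimulated) control.

    Conditions must share a stimulus and encode the dose as ``dose=<x>`` (the
    ``none`` condition is the 0 control). Donors missing the 0 control are
    listed in ``df.attrs["missing_control_donors"]`` rather than erroring.
    """

    def _dose(cond: str) -> float:
        if cond == "none":
            return 0.0
        if "dose=" in cond:
            return float(cond.split("dose=")[1])
        raise ValueError(f"condition {cond!r} carries no dose")

    rows = []
    seen: set[tuple[str, float]] = set()
    for r in responses:
        dose = _dose(r.condition)
        key = (r.donor_id, dose)
        if key in seen:
            raise ValueError(f"duplicate dose {dose:g} for donor {r.donor_id}")
        seen.add(key)
        rows.append(
            {"donor_id": r.donor_id, "dose": dose, "condition": r.condition,
             "mean_percent": r.mean, "sd_percent": r.sd, "n_replicates": r.n_replicates}
        )
    df = pd.DataFrame(rows).sort_values(["donor_id", "dose"], kind="mergesort").reset_index(drop=True)
    donors = df["donor_id"].unique()
    with_zero = set(df.loc[df["dose"] == 0, "donor_id"])
    df.attrs["missing_control_donors"] = sorted(set(donors) - with_zero)
    return df


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by enumeration of rank assignments.

    Returns (U of the first sample, p). The null is every way of assigning the
    pooled observations (midranks, so ties are handled) to the two groups with
    the observed sizes, each equally likely; the two-sided p-value is the
    probability of a U at least as far from its null mean n1*n2/2 as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    n_total = 0
    n_extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        n_total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            n_extreme += 1
    return u_obs, n_extreme / n_total


def compare_responders(
    low: Sequence[float],
    high: Sequence[float],
    alpha: float = 0.05,
    low_ids: Sequence[str] | None = None,
    high_ids: Sequence[str] | None = None,
) -> ResponderComparison:
    """Two-sided Mann-Whitney comparison of low vs high responder percents.

    Exact enumeration when the combined sample size is at most
    ``EXACT_MWU_MAX_N``; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both groups must be non-empty")
    low_ids = list(low_ids) if low_ids is not None else [f"low{i+1}" for i in range(len(low))]
    high_ids = list(high_ids) if high_ids is not None else [f"high{i+1}" for i in range(len(high))]
    overlap = set(low_ids) & set(high_ids)
    if overlap:
        raise ValueError(f"donor ids present in both groups: {sorted(overlap)}")

    if len(low) + len(high) <= EXACT_MWU_MAX_N:
        u, p = mann_whitney_exact(low, high)
        method = "exact"
    else:
        res = sps.mannwhitneyu(low, high, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return ResponderComparison(
        group_low=low_ids,
        group_high=high_ids,
        u_statistic=u,
        p_value=min(p, 1.0),
        significant=bool(p < alpha),
        alpha=alpha,
        method=method,
    )


def test_reproducibility(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> ReproducibilityTest:
    """Chi-square comparison of activated counts between two repeat experiments.

    Each argument is (n_activated, n_cells) for the matched condition. The
    statistic is the standard sum of (O-E)^2/E on the 2x2 activated /
    non-activated by experiment table, without continuity correction; if the
    expected table contains a zero, the Yates-corrected statistic is computed
    over the non-degenerate cells and flagged.
    """
    for act, tot in (counts_a, counts_b):
        if act < 0 or tot < 0 or act > tot:
            raise ValueError(f"invalid counts (activated={act}, total={tot})")
    table = np.array(
        [[counts_a[0], counts_a[1] - counts_a[0]],
         [counts_b[0], counts_b[1] - counts_b[0]]],
        dtype=float,
    )
    expected = sps.contingency.expected_freq(table) if table.sum() > 0 else np.zeros((2, 2))
    if np.any(expected == 0):
        nz = expected > 0
        stat = float((((np.abs(table - expected) - 0.5).clip(0) ** 2)[nz] / expected[nz]).sum())
        p = float(sps.chi2.sf(stat, df=1))
        return ReproducibilityTest(counts_a, counts_b, stat, p, yates_applied=True)
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ReproducibilityTest(counts_a, counts_b, float(stat), float(p), yates_applied=False)


def call_responder_groups(
    responses: Sequence[DonorResponse],
    method: str = "two_group_split",
    cutoff: float | None = None,
) -> ResponderGrouping:
    """Split donors into low and high responders by their mean percents.

    ``fixed_cutoff`` labels donors above the given percent high. The default
    ``two_group_split`` evaluates every split of the sorted means into a low
    and a high group and keeps the one minimising the total within-group sum
    of squares, breaking ties toward the smaller low group. Identical means
    for all donors give a flagged single-group result.
    """
    if len(responses) < 2:
        raise ValueError("at least two donors required")
    ids = [r.donor_id for r in responses]
    means = np.array([r.mean for r in responses], dtype=float)
    if np.ptp(means) == 0:
        return ResponderGrouping(low=sorted(ids), high=[], method=method, single_group=True)

    if method == "fixed_cutoff":
        if cutoff is None:
            raise ValueError("fixed_cutoff requires a cutoff percent")
        low = sorted(i for i, m in zip(ids, means) if m <= cutoff)
        high = sorted(i for i, m in zip(ids, means) if m > cutoff)
        return ResponderGrouping(low=low, high=high, method=method, cutoff=cutoff)
    if method != "two_group_split":
        raise ValueError("method must be 'fixed_cutoff' or 'two_group_split'")

    order = np.argsort(means, kind="mergesort")
    sorted_means = means[order]
    n = len(sorted_means)
    best_k, best_ss = 1, math.inf
    for k in range(1, n):
        lo, hi = sorted_means[:k], sorted_means[k:]
        ss = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        if ss < best_ss - 1e-12:  # ties keep the smaller low group (first k)
            best_ss, best_k = ss, k
    low = sorted(ids[i] for i in order[:best_k])
    high = sorted(ids[i] for i in order[best_k:])
    boundary = float((sorted_means[best_k - 1] + sorted_means[best_k]) / 2)
    return ResponderGrouping(low=low, high=high, method="two_group_split", cutoff=boundary)
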