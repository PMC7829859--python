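"""End-to-end validation routines on simulated plates.

These functions run the full simulate → segment → measure → summarise chain
against the generator's ground truth and return the recovery or calibration
quantities used to qualify the pipeline:

* translocation parameter recovery over a grid of true activated fractions,
* infection percent recovery at high GFP contrast,
* nucleus-count fidelity of the segmentation,
* type-I error of the chi-square reproducibility test under the null,
* power of the exact Mann-Whitney comparison for well-separated low/high
  responder groups.

All routines are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .infection import InfectionParams, score_infection
from .platestats import compare_responders, test_reproducibility
from .segment import SegmentationParams, derive_cytoplasm, segment_nuclei
from .simulate import SimParams, generate_field, well_truth_fractions
from .translocation import ScoringParams, measure_cells, summarize_well


def score_simulated_well(
    sim: SimParams,
    well_id: str,
    n_fields: int,
    seg: SegmentationParams | None = None,
    scoring: ScoringParams | None = None,
    condition: str = "sim",
) -> tuple["pd.Series", dict]:
    """Simulate and score one well; returns (summary row, ground-truth dict)."""
    seg = seg or SegmentationParams()
    scoring = scoring or ScoringParams()
    cells = []
    truths = []
    for fi in range(n_fields):
        field, truth = generate_field(sim, well_id, fi)
        truths.append(truth)
        nuc = segment_nuclei(field.channels["dna"], seg)
        cyt = derive_cytoplasm(nuc, seg)
        cells.extend(measure_cells(field, nuc, cyt, scoring))
    summary = summarize_well(cells, condition, scoring, well_id=well_id)
    truth = well_truth_fractions(truths)
    row = pd.Series(
        {
            "well": well_id,
            "n_cells_measured": summary.n_cells,
            "percent_activated": summary.percent_activated,
            "true_percent_activated": 100.0 * truth["true_activated_fraction"],
            "n_cells_true": truth["n_cells"],
        }
    )
    return row, truth


def recover_activated_fractions(
    fractions: list[float] | None = None,
    n_fields: int = 47,
    seed: int = 0,
    sim: SimParams | None = None,
) -> pd.DataFrame:
    """Percent-activated recovery across a grid of true activated fractions.

    One simulated well per fraction, scored end to end with default
    segmentation and scoring. The returned frame has one row per well with
    the measured percent, the nominal true percent (100 x the fraction
    parameter) and the absolute recovery error in percentage points.
    """
    fractions = fractions if fractions is not None else [0.1, 0.3, 0.5, 0.7, 0.9]
    base = sim or SimParams()
    rows = []
    for i, frac in enumerate(fractions):
        params = replace(base, activated_fraction=float(frac), seed=seed)
        well_id = f"B{i + 2:02d}"
        row, _ = score_simulated_well(params, well_id, n_fields)
        row["true_fraction"] = frac
        row["abs_error_pp"] = abs(row["percent_activated"] - 100.0 * frac)
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def recover_infected_fraction(
    infected_fraction: float = 0.5,
    n_fields: int = 47,
    seed: int = 0,
    sim: SimParams | None = None,
) -> pd.Series:
    """Percent-infected recovery for one simulated well at high GFP contrast."""
    base = sim or SimParams(channels=("dna", "gfp"))
    params = replace(base, infected_fraction=float(infected_fraction), seed=seed)
    seg = SegmentationParams()
    inf = InfectionParams()
    n_nuclei = 0
    n_pos = 0
    truths = []
    for fi in range(n_fields):
        field, truth = generate_field(params, "C03", fi)
        truths.append(truth)
        nuc = segment_nuclei(field.channels["dna"], seg)
        calls = score_infection(field, nuc, inf)
        n_nuclei += nuc.n_objects
        n_pos += sum(c.infected for c in calls)
    percent = 100.0 * n_pos / n_nuclei if n_nuclei else float("nan")
    truth = well_truth_fractions(truths)
    return pd.Series(
        {
            "n_nuclei": n_nuclei,
            "percent_infected": percent,
            "true_percent_infected": 100.0 * truth["true_infected_fraction"],
            "abs_error_pp": abs(percent - 100.0 * infected_fraction),
        }
    )


def segmentation_count_accuracy(
    n_fields: int = 50, seed: int = 0, sim: SimParams | None = None
) -> pd.DataFrame:
    """Detected vs true nucleus counts over non-clumped fields.

    Border exclusion is off so the detected population matches the ground
    truth census; the simulator places whole cells inside the field.
    """
    params = replace(sim or SimParams(), seed=seed)
    seg = SegmentationParams(border_policy="keep")
    rows = []
    for fi in range(n_fields):
        field, truth = generate_field(params, "D04", fi)
        nuc = segment_nuclei(field.channels["dna"], seg)
        rows.append({"field": fi, "detected": nuc.n_objects, "true": truth.n_cells})
    df = pd.DataFrame(rows)
    df.attrs["total_detected"] = int(df["detected"].sum())
    df.attrs["total_true"] = int(df["true"].sum())
    return df


def chisq_type1_rate(
    n_repeats: int = 1000,
    n_cells: int = 500,
    p_activated: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null chi-square reproducibility tests rejecting at alpha.

    Both "experiments" draw activated counts from the same binomial, so the
    rejection rate estimates the test's type-I error (nominally alpha).
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_repeats):
        a = int(rng.binomial(n_cells, p_activated))
        b = int(rng.binomial(n_cells, p_activated))
        res = test_reproducibility((a, n_cells), (b, n_cells))
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_repeats


def mannwhitney_power(
    n_repeats: int = 200,
    n_per_group: int = 6,
    low_dist: tuple[float, float] = (40.0, 5.0),
    high_dist: tuple[float, float] = (85.0, 4.0),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power of the exact Mann-Whitney test for separated responder groups.

    Donor mean percents are drawn from normal distributions centred on the
    typical low (~40%) and high (~85%) responder levels, clipped to [0, 100].
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_repeats):
        low = np.clip(rng.normal(*low_dist, size=n_per_group), 0, 100)
        high = np.clip(rng.normal(*high_dist, size=n_per_group), 0, 100)
        res = compare_responders(low, high, alpha=alpha)
        if res.significant:
            hits += 1
    return hits / n_repeats
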