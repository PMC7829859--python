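"""Per-cell NF-κB translocation scoring and per-well activation summaries.

Each cell's readout is the ratio of the mean signal intensity per pixel in
its nucleus mask to that in its cytoplasm mask. Cells are classified with two
strict thresholds: a ratio above 1.2 marks an activated (stimulated) cell,
a ratio below 1.0 a non-activated one; cells in the closed band [1.0, 1.2]
are intermediate. A well is summarised as the percentage of activated cells;
by default intermediates stay in the denominator (whole-population percent),
with an alternative policy that drops them from both counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segment import LabeledMask
from .simulate import FieldImage

log = logging.getLogger(__name__)

ACTIVATED = "activated"
NON_ACTIVATED = "non_activated"
INTERMEDIATE = "intermediate"

INTERMEDIATE_POLICIES = ("exclude_from_numerator_keep_in_denominator", "drop_from_both")
BACKGROUND_MODES = ("none", "field_median")


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds and measurement settings for translocation scoring.

    activation_threshold : nucleus:cytoplasm ratio above which a cell is
        activated (strict inequality). Default 1.2.
    non_activation_threshold : ratio below which a cell is non-activated
        (strict inequality). Default 1.0.
    intermediate_policy : how cells in [non_activation, activation] enter the
        well percentage; default keeps them in the denominator only.
    background_subtraction : "none" (default) or "field_median", which
        subtracts the per-field median of the signal channel before measuring.
    """

    activation_threshold: float = 1.2
    non_activation_threshold: float = 1.0
    intermediate_policy: str = "exclude_from_numerator_keep_in_denominator"
    background_subtraction: str = "none"

    def validate(self) -> None:
        if not (math.isfinite(self.activation_threshold) and math.isfinite(self.non_activation_threshold)):
            raise ValueError("thresholds must be finite")
        if self.non_activation_threshold > self.activation_threshold:
            raise ValueError(
                "non_activation_threshold must not exceed activation_threshold "
                f"({self.non_activation_threshold} > {self.activation_threshold})"
            )
        if self.intermediate_policy not in INTERMEDIATE_POLICIES:
            raise ValueError(f"intermediate_policy must be one of {INTERMEDIATE_POLICIES}")
        if self.background_subtraction not in BACKGROUND_MODES:
            raise ValueError(f"background_subtraction must be one of {BACKGROUND_MODES}")


@dataclass(frozen=True)
class CellMeasurement:
    """Compartment intensities and classification of one cell."""

    cell_id: int
    well_id: str
    field_index: int
    nucleus_mean: float
    cytoplasm_mean: float
    nc_ratio: float
    activation_class: str


@dataclass
class WellSummary:
    """Counts and percent-activated for one well under one condition.

    ``percent_activated`` is NaN (flagged, never silently 0) when no cells
    were measured. ``n_cells`` is the denominator actually used, which under
    the drop_from_both policy excludes intermediate cells.
    """

    well_id: str
    condition: str
    n_cells: int
    n_activated: int
    percent_activated: float
    n_fields_used: int
    n_intermediate: int = 0
    intermediate_policy: str = "exclude_from_numerator_keep_in_denominator"


def classify_ratio(nc_ratio: float, params: ScoringParams) -> str:
    """Three-way classification of a nucleus:cytoplasm ratio.

    Strict inequalities on both sides: a ratio exactly at the activation
    threshold is not activated, and one exactly at the non-activation
    threshold is not non-activated.
    """
    if not math.isfinite(nc_ratio):
        raise ValueError(f"nc_ratio must be finite, got {nc_ratio}")
    if nc_ratio > params.activation_threshold:
        return ACTIVATED
    if nc_ratio < params.non_activation_threshold:
        return NON_ACTIVATED
    return INTERMEDIATE


def classify_activation(measurement: CellMeasurement, params: ScoringParams) -> str:
    """Classification of a measured cell; see :func:`classify_ratio`."""
    return classify_ratio(measurement.nc_ratio, params)


def measure_cells(
    field: FieldImage,
    nucleus_mask: LabeledMask,
    cytoplasm_mask: LabeledMask,
    params: ScoringParams,
    channel: str = "nfkb",
) -> list[CellMeasurement]:
    """Measure mean signal per pixel in both compartments of every cell.

    One measurement is returned per label present in both masks. The mean is
    the sum of signal-channel pixel values in the compartment divided by its
    pixel count, after the configured background subtraction. Cells whose
    cytoplasm mean is <= 0 after subtraction are dropped with a logged count.
    """
    params.validate()
    if channel not in field.channels:
        raise ValueError(f"signal channel {channel!r} missing from field (has {sorted(field.channels)})")
    signal = field.channels[channel].astype(float)
    nuc, cyt = nucleus_mask.labels, cytoplasm_mask.labels
    if nuc.shape != signal.shape or cyt.shape != signal.shape:
        raise ValueError(
            f"mask/image shape mismatch: image {signal.shape}, "
            f"nucleus {nuc.shape}, cytoplasm {cyt.shape}"
        )
    if params.background_subtraction == "field_median":
        signal = signal - np.median(signal)

    ids = np.intersect1d(nucleus_mask.label_ids, cytoplasm_mask.label_ids)
    if ids.size == 0:
        return []
    nuc_means = ndi.mean(signal, labels=nuc, index=ids)
    cyt_means = ndi.mean(signal, labels=cyt, index=ids)

    out: list[CellMeasurement] = []
    n_dropped = 0
    for cid, nm, cm in zip(ids, nuc_means, cyt_means):
        if cm <= 0:
            n_dropped += 1
            continue
        ratio = float(nm / cm)
        out.append(
            CellMeasurement(
                cell_id=int(cid),
                well_id=field.well_id,
                field_index=field.field_index,
                nucleus_mean=float(nm),
                cytoplasm_mean=float(cm),
                nc_ratio=ratio,
                activation_class=classify_ratio(ratio, params),
            )
        )
    if n_dropped:
        log.warning(
            "%s field %d: dropped %d cell(s) with non-positive cytoplasm mean",
            field.well_id, field.field_index, n_dropped,
        )
    return out


def summarize_well(
    cells: list[CellMeasurement],
    condition: str,
    params: ScoringParams,
    well_id: str | None = None,
) -> WellSummary:
    """Aggregate all measurements of one well into a percent-activated summary."""
    params.validate()
    wells = {c.well_id for c in cells}
    if len(wells) > 1:
        raise ValueError(f"cells span multiple wells: {sorted(wells)}")
    if well_id is None:
        if not wells:
            raise ValueError("well_id required for an empty cell list")
        well_id = wells.pop()

    n_act = sum(c.activation_class == ACTIVATED for c in cells)
    n_int = sum(c.activation_class == INTERMEDIATE for c in cells)
    if params.intermediate_policy == "drop_from_both":
        n_total = len(cells) - n_int
    else:
        n_total = len(cells)
    percent = 100.0 * n_act / n_total if n_total > 0 else float("nan")
    if n_total == 0:
        log.warning("well %s: no measurable cells, percent_activated undefined", well_id)
    return WellSummary(
        well_id=well_id,
        condition=condition,
        n_cells=n_total,
        n_activated=n_act,
        percent_activated=percent,
        n_fields_used=len({c.field_index for c in cells}),
        n_intermediate=n_int,
        intermediate_policy=params.intermediate_policy,
    )


def threshold_flip_scan(
    direction: str,
    resolution: float = 0.001,
    params: ScoringParams | None = None,
    ratio_range: tuple[float, float] = (0.0, 2.0),
) -> float:
    """Locate a classification boundary by sweeping synthetic ratios.

    Sweeps a grid of single-cell ratios at the given resolution and returns,
    for ``direction="activated"``, the smallest ratio classified activated
    minus one grid step, and for ``direction="non_activated"``, the largest
    ratio classified non-activated plus one grid step — i.e. the boundary
    ratio itself. Under default parameters the boundaries are 1.2 and 1.0.
    """
    if params is None:
        params = ScoringParams()
    params.validate()
    if direction not in (ACTIVATED, NON_ACTIVATED):
        raise ValueError("direction must be 'activated' or 'non_activated'")
    lo, hi = ratio_range
    n_steps = int(round((hi - lo) / resolution))
    # rounding keeps grid points exact at the printed precision (1.2, not 1.2000000000000002)
    grid = np.round(lo + resolution * np.arange(n_steps + 1), 12)
    classes = [classify_ratio(float(r), params) for r in grid]
    if direction == ACTIVATED:
        idx = next(i for i, c in enumerate(classes) if c == ACTIVATED)
        return float(np.round(grid[idx] - resolution, 12))
    idx = max(i for i, c in enumerate(classes) if c == NON_ACTIVATED)
    return float(np.round(grid[idx] + resolution, 12))
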