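"""Synthetic multi-channel fluorescence fields with exact per-cell ground truth.

The simulator emulates low-magnification (10x) images of sparsely plated
adherent fibroblasts as acquired by an automated plate microscope: a DNA
counterstain channel ("dna") showing round nuclei, an NF-κB immunostain
channel ("nfkb") whose per-cell nucleus:cytoplasm intensity ratio is drawn
from a two-component activated / resting mixture, and a reporter channel
("gfp") with nuclear-localised GFP in a controllable infected fraction.

Cells are rendered as a nuclear disk surrounded by a concentric cytoplasmic
annulus. The nucleus pixel value in the signal channel is ``ratio x (cytoplasm
pixel value)`` including the background floor, so that the true ratio of a
cell refers directly to the measured per-pixel mean ratio — a noiseless
render-and-measure round trip recovers ``true_ratio`` exactly.

Noise follows a standard fluorescence camera model: shot noise with variance
proportional to signal (Poisson statistics with a configurable gain) plus
additive Gaussian read noise. An optional multiplicative linear illumination
ramp models field non-uniformity.

Determinism: every field's random stream is derived from
``(seed, well row, well column, field index)`` via ``numpy.random.SeedSequence``
spawn keys, so any single field is regenerable in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .layout import PlateLayout, parse_well_id

VALID_CHANNELS = ("dna", "nfkb", "gfp")

#: fields acquired per well to cover roughly its entire surface
DEFAULT_FIELDS_PER_WELL = 47


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic field generator.

    Defaults emulate a 96-well plate seeded with ~6,000 cells per well imaged
    as 47 fields, i.e. an expected ~128 cells per field, with nuclei of ~6 px
    radius and a cytoplasm extending to ~14 px at a 10x-objective pixel scale
    (~1.3 um/px) — a flat fibroblast's cell body is much wider than its
    nucleus, which is what makes a perinuclear ring a valid cytoplasm sample.

    Attributes
    ----------
    field_shape : (height, width) in pixels.
    cells_per_field : Poisson mean of the per-field cell count.
    nucleus_radius : (mean, sd) of the nuclear radius in pixels.
    cytoplasm_outer_radius : (mean, sd) of the outer cytoplasm radius in
        pixels; the mean must exceed the nucleus radius mean.
    activated_fraction : probability that a cell is drawn from the activated
        mixture component.
    activated_ratio_dist : (mean, sd) of the true nucleus:cytoplasm ratio of
        activated cells; the mean must exceed 1.2.
    resting_ratio_dist : (mean, sd) for resting cells; mean below 1.
    infected_fraction : probability that a cell carries nuclear GFP.
    gfp_nuclear_intensity : (mean, sd) of the nuclear GFP signal (a.u.) of
        infected cells, added on top of background.
    dna_nuclear_intensity : DNA counterstain signal (a.u.) inside nuclei.
    cytoplasm_intensity : signal-channel cytoplasm intensity above background.
    background_level : additive background offset (a.u.) in every channel.
    shot_noise_scale : camera gain g; pixel variance = g * signal. 0 disables
        shot noise.
    read_noise_sd : additive Gaussian read noise sd (a.u.); 0 disables.
    illumination_gradient : relative amplitude in [0, 1) of a linear
        multiplicative ramp along the field width.
    clumping : allow cytoplasm annuli of neighbouring cells to overlap
        (segmentation stress test); nuclei never overlap.
    channels : channels to render; must include "dna".
    seed : master seed of the per-field seed tree.
    """

    field_shape: tuple[int, int] = (512, 512)
    cells_per_field: float = 128.0
    nucleus_radius: tuple[float, float] = (6.0, 0.75)
    cytoplasm_outer_radius: tuple[float, float] = (14.0, 1.0)
    activated_fraction: float = 0.0
    activated_ratio_dist: tuple[float, float] = (2.0, 0.2)
    resting_ratio_dist: tuple[float, float] = (0.7, 0.1)
    infected_fraction: float = 0.0
    gfp_nuclear_intensity: tuple[float, float] = (200.0, 20.0)
    dna_nuclear_intensity: float = 120.0
    cytoplasm_intensity: float = 100.0
    background_level: float = 8.0
    shot_noise_scale: float = 1.0
    read_noise_sd: float = 2.0
    illumination_gradient: float = 0.0
    clumping: bool = False
    channels: tuple[str, ...] = ("dna", "nfkb")
    seed: int = 0

    def validate(self) -> None:
        h, w = self.field_shape
        if h < 8 or w < 8:
            raise ValueError(f"field_shape too small: {self.field_shape}")
        for name in ("cells_per_field", "dna_nuclear_intensity", "cytoplasm_intensity",
                     "background_level", "shot_noise_scale", "read_noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("nucleus_radius", "cytoplasm_outer_radius",
                     "activated_ratio_dist", "resting_ratio_dist",
                     "gfp_nuclear_intensity"):
            mean, sd = getattr(self, name)
            if not (math.isfinite(mean) and math.isfinite(sd)) or mean <= 0 or sd < 0:
                raise ValueError(f"{name} must have positive finite mean and sd >= 0, got {(mean, sd)}")
        for name in ("activated_fraction", "infected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cytoplasm_outer_radius[0] <= self.nucleus_radius[0]:
            raise ValueError("cytoplasm outer radius mean must exceed nucleus radius mean")
        if not 0.0 <= self.illumination_gradient < 1.0:
            raise ValueError("illumination_gradient must lie in [0, 1)")
        if "dna" not in self.channels:
            raise ValueError("channels must include 'dna'")
        unknown = set(self.channels) - set(VALID_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth record of one simulated cell."""

    cell_id: int
    row: float
    col: float
    nucleus_radius: float
    cytoplasm_radius: float
    true_ratio: float
    true_activated: bool
    true_infected: bool


@dataclass
class FieldGroundTruth:
    """Per-field ground truth: one record per rendered cell."""

    well_id: str
    field_index: int
    cells: list[CellTruth] = dc_field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_activated(self) -> int:
        return sum(c.true_activated for c in self.cells)

    @property
    def n_infected(self) -> int:
        return sum(c.true_infected for c in self.cells)


@dataclass
class FieldImage:
    """One acquisition field: aligned per-channel intensity rasters."""

    well_id: str
    field_index: int
    channels: dict[str, np.ndarray]

    def validate(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for ch, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {ch!r} contains non-finite pixels")
            if arr.min() < 0:
                raise ValueError(f"channel {ch!r} contains negative pixels")


def field_rng(params: SimParams, well_id: str, field_index: int) -> np.random.Generator:
    """Random generator for one (well, field), independent of generation order."""
    row, col = parse_well_id(well_id)
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(row, col, field_index))
    return np.random.default_rng(ss)


def _place_cells(params: SimParams, rng: np.random.Generator) -> list[CellTruth]:
    """Dart-throwing placement without nucleus-nucleus overlap.

    Centers keep a full cytoplasm radius of clearance from the field border so
    every cell has a complete annulus. Under ``clumping`` only nuclei are kept
    disjoint; otherwise whole cells (outer radii) are separated by >= 2 px.
    """
    h, w = params.field_shape
    n = int(rng.poisson(params.cells_per_field))
    cells: list[CellTruth] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    max_attempts = 200 * max(n, 1)
    attempts = 0
    while len(cells) < n and attempts < max_attempts:
        attempts += 1
        r_nuc = max(2.0, rng.normal(*params.nucleus_radius))
        r_cyt = max(r_nuc + 1.0, rng.normal(*params.cytoplasm_outer_radius))
        margin = r_cyt + 1.0
        if 2 * margin >= min(h, w):
            break
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        sep_r = r_nuc + 1.0 if params.clumping else r_cyt + 1.0
        if len(radii):
            d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            if np.any(d < radii + sep_r):
                continue
        activated = bool(rng.random() < params.activated_fraction)
        dist = params.activated_ratio_dist if activated else params.resting_ratio_dist
        ratio = float(np.clip(rng.normal(*dist), 0.05, None))
        infected = bool(rng.random() < params.infected_fraction)
        cells.append(
            CellTruth(
                cell_id=len(cells) + 1,
                row=float(cy),
                col=float(cx),
                nucleus_radius=float(r_nuc),
                cytoplasm_radius=float(r_cyt),
                true_ratio=ratio,
                true_activated=activated,
                true_infected=infected,
            )
        )
        centers = np.vstack([centers, [cy, cx]])
        radii = np.append(radii, sep_r)
    return cells


def _paint(arr: np.ndarray, cy: float, cx: float, r_in: float, r_out: float, value: float) -> None:
    """Assign `value` to pixels with r_in < distance(center) <= r_out."""
    h, w = arr.shape
    r0 = max(0, int(math.floor(cy - r_out)))
    r1 = min(h, int(math.ceil(cy + r_out)) + 1)
    c0 = max(0, int(math.floor(cx - r_out)))
    c1 = min(w, int(math.ceil(cx + r_out)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - cy, xx - cx)
    sel = (d <= r_out) & (d > r_in)
    sub = arr[r0:r1, c0:c1]
    sub[sel] = value


def generate_field(
    params: SimParams, well_id: str, field_index: int
) -> tuple[FieldImage, FieldGroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic given ``(params.seed, well_id, field_index)``. The dna
    channel holds disk-shaped nuclei at the ground-truth centres; the signal
    channel realises each cell's ``true_ratio`` before noise.
    """
    params.validate()
    rng = field_rng(params, well_id, field_index)
    cells = _place_cells(params, rng)
    truth = FieldGroundTruth(well_id=well_id, field_index=field_index, cells=cells)

    h, w = params.field_shape
    bg = params.background_level
    clean: dict[str, np.ndarray] = {
        ch: np.full((h, w), bg, dtype=float) for ch in params.channels
    }
    # per-cell GFP draws happen for every cell so the stream does not depend
    # on the infected flags
    gfp_levels = rng.normal(*params.gfp_nuclear_intensity, size=len(cells))
    for cell, gfp_level in zip(cells, gfp_levels):
        cy, cx = cell.row, cell.col
        if "dna" in clean:
            _paint(clean["dna"], cy, cx, -1.0, cell.nucleus_radius, bg + params.dna_nuclear_intensity)
        if "nfkb" in clean:
            cyto_val = bg + params.cytoplasm_intensity
            _paint(clean["nfkb"], cy, cx, cell.nucleus_radius, cell.cytoplasm_radius, cyto_val)
            _paint(clean["nfkb"], cy, cx, -1.0, cell.nucleus_radius, cell.true_ratio * cyto_val)
        if "gfp" in clean and cell.true_infected:
            _paint(clean["gfp"], cy, cx, -1.0, cell.nucleus_radius, bg + max(float(gfp_level), 0.0))

    if params.illumination_gradient > 0:
        ramp = 1.0 + params.illumination_gradient * (2.0 * np.arange(w) / (w - 1) - 1.0)
        for arr in clean.values():
            arr *= ramp[np.newaxis, :]

    noisy: dict[str, np.ndarray] = {}
    for ch in params.channels:  # fixed order = params.channels for determinism
        img = clean[ch]
        if params.shot_noise_scale > 0:
            g = params.shot_noise_scale
            img = rng.poisson(img / g).astype(float) * g
        if params.read_noise_sd > 0:
            img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
        noisy[ch] = np.clip(img, 0.0, None)

    field = FieldImage(well_id=well_id, field_index=field_index, channels=noisy)
    field.validate()
    return field, truth


def generate_plate(
    layout: PlateLayout,
    params_per_condition: Mapping[str, SimParams],
    fields_per_well: int = DEFAULT_FIELDS_PER_WELL,
) -> Iterator[tuple[FieldImage, FieldGroundTruth]]:
    """Yield every field of a plate, well by well, in layout order.

    ``params_per_condition`` maps each condition label used in the layout to
    its simulation parameters; all fields share the layout's seeding through
    ``SimParams.seed``, so two plates generated from the same layout and
    parameter sets are identical.
    """
    missing = [w for w, ann in layout.wells.items() if ann.condition not in params_per_condition]
    if missing:
        raise KeyError(f"no SimParams for condition of wells {missing}")
    if fields_per_well < 1:
        raise ValueError("fields_per_well must be >= 1")
    for well_id in layout.well_ids():
        cond = layout.wells[well_id].condition
        params = params_per_condition[cond]
        for field_index in range(fields_per_well):
            yield generate_field(params, well_id, field_index)


def well_truth_fractions(truths: Sequence[FieldGroundTruth]) -> dict[str, float]:
    """Aggregate field truths of one well into true activated/infected fractions."""
    n = sum(t.n_cells for t in truths)
    act = sum(t.n_activated for t in truths)
    inf = sum(t.n_infected for t in truths)
    return {
        "n_cells": n,
        "true_activated_fraction": act / n if n else float("nan"),
        "true_infected_fraction": inf / n if n else float("nan"),
    }
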