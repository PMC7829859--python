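import numpy as np
import pytest

from hcsquant.segment import SegmentationParams, derive_cytoplasm, segment_nuclei
from hcsquant.simulate import FieldImage, SimParams, generate_field
from hcsquant.translocation import ScoringParams, measure_cells


@pytest.fixture
def fast_sim():
    """Small fields for quick end-to-end tests (~40 cells per field)."""
    return SimParams(field_shape=(320, 320), cells_per_field=40.0, seed=7)


@pytest.fixture
def noiseless_sim(fast_sim):
    from dataclasses import replace

    return replace(fast_sim, shot_noise_scale=0.0, read_noise_sd=0.0)


@pytest.fixture
def seg_params():
    return SegmentationParams()


def truth_masks(truth, shape):
    """Ground-truth nucleus and cytoplasm label rasters from simulator records."""
    nuc = np.zeros(shape, dtype=np.int32)
    cyt = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for c in truth.cells:
        d = np.hypot(yy - c.row, xx - c.col)
        nuc[d <= c.nucleus_radius] = c.cell_id
        cyt[(d > c.nucleus_radius) & (d <= c.cytoplasm_radius)] = c.cell_id
    return nuc, cyt


def score_field(sim, well_id="B02", field_index=0, scoring=None, seg=None):
    """Simulate one field and run segmentation + measurement on it."""
    field, truth = generate_field(sim, well_id, field_index)
    seg = seg or SegmentationParams()
    nuc = segment_nuclei(field.channels["dna"], seg)
    cyt = derive_cytoplasm(nuc, seg)
    cells = measure_cells(field, nuc, cyt, scoring or ScoringParams())
    return field, truth, nuc, cyt, cells


def make_field(channels, well_id="B02", field_index=0):
    return FieldImage(well_id=well_id, field_index=field_index, channels=channels)
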