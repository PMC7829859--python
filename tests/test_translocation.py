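"""Per-cell ratio measurement, three-way classification, well summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcsquant.segment import LabeledMask
from hcsquant.translocation import (
    ACTIVATED,
    INTERMEDIATE,
    NON_ACTIVATED,
    CellMeasurement,
    ScoringParams,
    classify_ratio,
    measure_cells,
    summarize_well,
    threshold_flip_scan,
)

from conftest import make_field, score_field


def _uniform_cell_field():
    """One cell with uniform nucleus value 12 and cytoplasm value 10."""
    sig = np.full((32, 32), 2.0)
    nuc = np.zeros((32, 32), dtype=np.int32)
    cyt = np.zeros((32, 32), dtype=np.int32)
    yy, xx = np.mgrid[0:32, 0:32]
    d = np.hypot(yy - 16, xx - 16)
    nuc[d <= 5] = 1
    cyt[(d > 5) & (d <= 9)] = 1
    sig[nuc == 1] = 12.0
    sig[cyt == 1] = 10.0
    field = make_field({"dna": np.zeros((32, 32)), "nfkb": sig})
    return field, LabeledMask("nucleus", nuc), LabeledMask("cytoplasm", cyt)


def test_uniform_compartments_give_exact_means_and_ratio():
    field, nuc, cyt = _uniform_cell_field()
    (m,) = measure_cells(field, nuc, cyt, ScoringParams())
    assert m.nucleus_mean == pytest.approx(12.0)
    assert m.cytoplasm_mean == pytest.approx(10.0)
    assert m.nc_ratio == pytest.approx(1.2)
    # exactly at the activation threshold: strictly NOT activated
    assert m.activation_class == INTERMEDIATE


def test_measurements_match_brute_force_pixel_loop(fast_sim):
    """Every compartment mean and ratio equals an independent per-pixel
    accumulation to relative tolerance 1e-9."""
    field, _, nuc, cyt, cells = score_field(fast_sim)
    assert len(cells) > 10
    sig = field.channels["nfkb"]

    def brute_means(labels):
        sums, counts = {}, {}
        h, w = labels.shape
        for i in range(h):
            for j in range(w):
                lab = int(labels[i, j])
                if lab > 0:
                    sums[lab] = sums.get(lab, 0.0) + float(sig[i, j])
                    counts[lab] = counts.get(lab, 0) + 1
        return {k: sums[k] / counts[k] for k in sums}

    nuc_means = brute_means(nuc.labels)
    cyt_means = brute_means(cyt.labels)
    for c in cells:
        assert c.nucleus_mean == pytest.approx(nuc_means[c.cell_id], rel=1e-9)
        assert c.cytoplasm_mean == pytest.approx(cyt_means[c.cell_id], rel=1e-9)
        assert c.nc_ratio == pytest.approx(nuc_means[c.cell_id] / cyt_means[c.cell_id], rel=1e-9)


def test_empty_field_gives_empty_measurements():
    empty = LabeledMask("nucleus", np.zeros((16, 16), np.int32))
    empty_c = LabeledMask("cytoplasm", np.zeros((16, 16), np.int32))
    field = make_field({"dna": np.zeros((16, 16)), "nfkb": np.ones((16, 16))})
    assert measure_cells(field, empty, empty_c, ScoringParams()) == []


def test_shape_mismatch_is_structural_error():
    field, nuc, cyt = _uniform_cell_field()
    bad = LabeledMask("cytoplasm", np.zeros((16, 16), np.int32))
    with pytest.raises(ValueError, match="shape mismatch"):
        measure_cells(field, nuc, bad, ScoringParams())


def test_missing_signal_channel_error():
    field, nuc, cyt = _uniform_cell_field()
    del field.channels["nfkb"]
    with pytest.raises(ValueError, match="nfkb"):
        measure_cells(field, nuc, cyt, ScoringParams())


def test_nonpositive_cytoplasm_mean_dropped(caplog):
    import logging

    field, nuc, cyt = _uniform_cell_field()
    field.channels["nfkb"] = np.zeros_like(field.channels["nfkb"])
    with caplog.at_level(logging.WARNING, logger="hcsquant.translocation"):
        out = measure_cells(field, nuc, cyt, ScoringParams())
    assert out == []
    assert any("dropped" in r.message for r in caplog.records)


@pytest.mark.parametrize(
    "ratio,expected",
    [
        (1.3, ACTIVATED),
        (0.9, NON_ACTIVATED),
        (1.1, INTERMEDIATE),
        (1.2, INTERMEDIATE),  # "higher at 1.2": strict
        (1.0, INTERMEDIATE),  # "less than 1": strict
        (1.2000001, ACTIVATED),
        (0.9999999, NON_ACTIVATED),
    ],
)
def test_three_way_classification(ratio, expected):
    assert classify_ratio(ratio, ScoringParams()) == expected


def test_nonfinite_ratio_rejected():
    with pytest.raises(ValueError):
        classify_ratio(float("nan"), ScoringParams())


def _fake_cells(ratios, well="B02"):
    return [
        CellMeasurement(
            cell_id=i + 1, well_id=well, field_index=0, nucleus_mean=r, cytoplasm_mean=1.0,
            nc_ratio=r, activation_class=classify_ratio(r, ScoringParams()),
        )
        for i, r in enumerate(ratios)
    ]


def test_summary_intermediate_policies():
    ratios = [1.5] * 60 + [1.1] * 10 + [0.5] * 30
    cells = _fake_cells(ratios)
    keep = summarize_well(cells, "c", ScoringParams())
    assert keep.n_cells == 100 and keep.n_activated == 60
    assert keep.percent_activated == pytest.approx(60.0)
    drop = summarize_well(cells, "c", ScoringParams(intermediate_policy="drop_from_both"))
    assert drop.n_cells == 90
    assert drop.percent_activated == pytest.approx(100 * 60 / 90)


def test_zero_cell_summary_flagged_not_zero():
    s = summarize_well([], "c", ScoringParams(), well_id="B02")
    assert s.n_cells == 0
    assert np.isnan(s.percent_activated)


def test_summary_rejects_mixed_wells():
    cells = _fake_cells([1.5], well="B02") + _fake_cells([0.5], well="B03")
    with pytest.raises(ValueError, match="multiple wells"):
        summarize_well(cells, "c", ScoringParams())


def test_classification_scale_invariant(fast_sim):
    """Multiplying the signal channel by a positive constant leaves every
    cell's class unchanged (no background subtraction)."""
    field, _, nuc, cyt, cells = score_field(fast_sim)
    field.channels["nfkb"] = field.channels["nfkb"] * 3.7
    from hcsquant.translocation import measure_cells as mc

    scaled = mc(field, nuc, cyt, ScoringParams())
    assert [c.activation_class for c in scaled] == [c.activation_class for c in cells]


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    ratios=st.lists(st.floats(0.05, 3.0), min_size=1, max_size=40),
    shift=st.floats(0.0, 1.0),
)
def test_percent_activated_monotone_under_ratio_shift(ratios, shift):
    params = ScoringParams()
    base = summarize_well(_fake_cells(ratios), "c", params)
    shifted = summarize_well(_fake_cells([r + shift for r in ratios]), "c", params)
    assert shifted.percent_activated >= base.percent_activated
    assert 0.0 <= base.percent_activated <= 100.0


def test_invalid_threshold_ordering_rejected():
    with pytest.raises(ValueError):
        ScoringParams(activation_threshold=1.0, non_activation_threshold=1.2).validate()


def test_flip_scan_recovers_printed_boundaries():
    assert threshold_flip_scan("activated", 0.001) == pytest.approx(1.2, abs=1e-12)
    assert threshold_flip_scan("non_activated", 0.001) == pytest.approx(1.0, abs=1e-12)


def test_flip_scan_collapsed_thresholds_coincide():
    params = ScoringParams(activation_threshold=1.1, non_activation_threshold=1.1)
    a = threshold_flip_scan("activated", 0.001, params)
    b = threshold_flip_scan("non_activated", 0.001, params)
    assert a == b == pytest.approx(1.1, abs=1e-12)
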