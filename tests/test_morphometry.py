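import math

import numpy as np
import pytest

from deepmarrow import morphometry, phantom
from deepmarrow.core_io import ImageStack
from deepmarrow.morphometry import (
    CellObject,
    classify_by_volume,
    coloc_gate,
    cortical_thickness,
    segment_cells,
    sphere_volume,
    thg_hi_classify,
    thg_threshold,
)


def _paint_sphere(vol, centre, radius, value):
    zz, yy, xx = np.indices(vol.shape)
    m = ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2
         + (xx - centre[2]) ** 2) <= radius ** 2
    vol[m] = value
    return m


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_single_ellipsoid_volume_within_five_percent():
    vol = np.zeros((28, 28, 28), dtype=np.float32)
    r = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)  # sphere of 1000 μm³
    _paint_sphere(vol, (14, 14, 14), r, 400.0)
    stack = ImageStack(vol, (1.0, 1.0, 1.0), ["tdRFP"])
    _, cells = segment_cells(stack, "tdRFP")
    assert len(cells) == 1
    assert cells[0].volume == pytest.approx(1000.0, rel=0.05)


def test_touching_spheres_are_split_by_watershed():
    vol = np.zeros((24, 24, 40), dtype=np.float32)
    _paint_sphere(vol, (12, 12, 13), 6.0, 400.0)
    _paint_sphere(vol, (12, 12, 25), 6.0, 400.0)
    stack = ImageStack(vol, (1.0, 1.0, 1.0), ["tdRFP"])
    _, cells = segment_cells(stack, "tdRFP", seed_diameter=7.5)
    assert len(cells) == 2


def test_empty_foreground_returns_empty_list():
    stack = ImageStack(np.zeros((6, 24, 24), dtype=np.float32), (1, 1, 1),
                       ["tdRFP"])
    labels, cells = segment_cells(stack, "tdRFP")
    assert cells == [] and labels.max() == 0


def test_extreme_anisotropy_refused():
    stack = ImageStack(np.zeros((4, 16, 16), dtype=np.float32),
                       (12.0, 1.0, 1.0), ["tdRFP"])
    with pytest.raises(ValueError):
        segment_cells(stack, "tdRFP")


def test_phantom_cell_count_recovered():
    """Object counts on default-noise phantoms track the generated cell count."""
    errs = []
    for s in range(5):
        cells = phantom.CellPopulationSpec(n_b=0, n_plasma=30)
        stack, gt = phantom.generate_phantom(
            cells=cells, shape=(9, 160, 160), spacing=(3.0, 1.5, 1.5), seed=s)
        _, objs = segment_cells(stack, "tdRFP")
        errs.append(len(objs) - 30)
    assert np.mean(np.abs(errs)) <= 1.5
    assert max(abs(e) for e in errs) <= 3


# ---------------------------------------------------------------------------
# volume classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("volume,expected", [
    (300.0, "B"),
    (sphere_volume(20.0), "plasma"),   # 4188.79 μm³, inside the 4189 gate
    (50.0, "excluded"),
    (500.0, "plasma"),                 # boundary belongs to plasma
    (65.0, "B"),
    (4189.0, "plasma"),
    (4200.0, "excluded"),
])
def test_volume_gates(volume, expected):
    cell = CellObject(label=1, volume=volume, centroid=(0, 0, 0))
    classify_by_volume([cell])
    assert cell.cell_class == expected


def test_printed_gate_bounds_are_sphere_volumes():
    assert sphere_volume(20.0) == pytest.approx(4188.79, abs=0.01)
    assert sphere_volume(5.0) == pytest.approx(65.45, abs=0.01)


# ---------------------------------------------------------------------------
# THG^hi classification
# ---------------------------------------------------------------------------

def test_uniform_thg_image_yields_no_hi_cells():
    shape = (6, 24, 24)
    rfp = np.zeros(shape, dtype=np.float32)
    _paint_sphere(rfp, (3, 12, 12), 5.0, 400.0)
    thg = np.full(shape, 7.0, dtype=np.float32)
    stack = ImageStack(np.stack([rfp, thg]), (1, 1, 1), ["tdRFP", "THG"])
    labels, cells = segment_cells(stack, "tdRFP")
    with pytest.warns(UserWarning):
        thg_hi_classify(stack, labels, cells)
    assert all(c.thg_class == "lo" for c in cells)


def test_cell_holding_top_percent_voxels_is_the_only_hi():
    shape = (8, 32, 32)
    rfp = np.zeros(shape, dtype=np.float32)
    m1 = _paint_sphere(rfp, (4, 8, 8), 5.0, 400.0)
    m2 = _paint_sphere(rfp, (4, 24, 24), 5.0, 400.0)
    rng = np.random.default_rng(0)
    thg = rng.uniform(0.0, 10.0, shape).astype(np.float32)
    # >1% of all voxels are bright and sit inside cell 1, with graded values so
    # that the 99th-percentile threshold falls strictly among them
    bright = np.argwhere(m1)[:120]
    for i, p in enumerate(bright):
        thg[tuple(p)] = 400.0 + 2.0 * i
    stack = ImageStack(np.stack([rfp, thg]), (1, 1, 1), ["tdRFP", "THG"])
    labels, cells = segment_cells(stack, "tdRFP")
    assert len(cells) == 2
    thr = thg_hi_classify(stack, labels, cells, percentile=99.0)
    # brute-force oracle for the threshold itself
    assert thr.value == pytest.approx(float(np.percentile(thg, 99.0)))
    hi = [c for c in cells if c.thg_class == "hi"]
    assert len(hi) == 1
    assert hi[0].centroid[1] < 16  # the cell that holds the bright voxels


def test_threshold_monotone_in_percentile(small_phantom):
    stack, gt = small_phantom
    t90 = thg_threshold(stack, percentile=90.0, tissue_mask=gt.tissue_mask)
    t99 = thg_threshold(stack, percentile=99.0, tissue_mask=gt.tissue_mask)
    t999 = thg_threshold(stack, percentile=99.9, tissue_mask=gt.tissue_mask)
    assert t90.value <= t99.value <= t999.value


def test_raising_percentile_never_grows_hi_set(small_phantom):
    stack, gt = small_phantom
    counts = []
    for pct in (95.0, 99.0, 99.8):
        labels, cells = segment_cells(stack, "tdRFP")
        thg_hi_classify(stack, labels, cells, percentile=pct,
                        tissue_mask=gt.tissue_mask)
        counts.append(sum(1 for c in cells if c.thg_class == "hi"))
    assert counts[0] >= counts[1] >= counts[2]


def test_hi_call_stable_for_min_voxel_choices(small_phantom):
    """Granule-bearing cells carry >= 3 bright voxels, so the presence rule is
    stable across the documented min-voxel settings."""
    stack, gt = small_phantom
    labels, cells = segment_cells(stack, "tdRFP")
    calls = []
    for m in (1, 2, 3, 4, 5):
        thg_hi_classify(stack, labels, cells, min_voxels=m,
                        tissue_mask=gt.tissue_mask)
        calls.append(sum(1 for c in cells if c.thg_class == "hi"))
    # granule-bearing cells carry >= 3 granules, so the call is identical for
    # m in {1, 2, 3} and can only shrink beyond that
    assert calls[0] == calls[1] == calls[2]
    assert calls[2] >= calls[3] >= calls[4]


def test_percentile_bounds_validated():
    with pytest.raises(ValueError):
        morphometry.ThgThreshold(percentile=0.0, value=1.0, channel="THG")


# ---------------------------------------------------------------------------
# colocalization gating
# ---------------------------------------------------------------------------

def _coloc_setup(ref_means, thg_classes, control_value=10.0):
    shape = (4, 16, 16)
    ref = np.full(shape, 1.0, dtype=np.float32)
    ref[:, :4, :] = control_value
    stack = ImageStack(ref[None], (1, 1, 1), ["ER"])
    control = np.zeros(shape, bool)
    control[:, :4, :] = True
    cells = []
    for i, (m, t) in enumerate(zip(ref_means, thg_classes), start=1):
        c = CellObject(label=i, volume=800.0, centroid=(0, 0, 0))
        c.channel_mean["ER"] = m
        c.thg_class = t
        cells.append(c)
    return stack, cells, control


def test_zero_reference_channel_all_negative():
    stack, cells, control = _coloc_setup([0.0, 0.0], ["hi", "lo"],
                                         control_value=0.0)
    stack.voxels[:] = 0.0
    res = coloc_gate(stack, cells, "ER", control)
    assert res.n_positive == 0
    assert res.fraction_thg_hi_positive == 0.0
    assert res.fraction_positive_thg_hi is None  # undefined denominator flagged


def test_perfect_concordance_both_fractions_one():
    stack, cells, control = _coloc_setup([50.0, 50.0, 5.0], ["hi", "hi", "lo"])
    res = coloc_gate(stack, cells, "ER", control)
    assert res.fraction_thg_hi_positive == 1.0
    assert res.fraction_positive_thg_hi == 1.0


def test_detection_limit_is_control_region_max():
    stack, cells, control = _coloc_setup([15.0, 5.0], ["hi", "hi"],
                                         control_value=10.0)
    res = coloc_gate(stack, cells, "ER", control)
    assert res.detection_limit == 10.0
    assert res.fraction_thg_hi_positive == 0.5


def test_coloc_invariant_to_joint_scaling():
    stack, cells, control = _coloc_setup([15.0, 5.0, 30.0], ["hi", "hi", "lo"])
    r0 = coloc_gate(stack, cells, "ER", control)
    stack2 = stack.with_voxels(stack.voxels * 3.0)
    for c in cells:
        c.channel_mean["ER"] *= 3.0
    r1 = coloc_gate(stack2, cells, "ER", control)
    assert r0.fraction_thg_hi_positive == r1.fraction_thg_hi_positive


def test_empty_control_region_rejected():
    stack, cells, control = _coloc_setup([1.0], ["hi"])
    with pytest.raises(ValueError):
        coloc_gate(stack, cells, "ER", np.zeros_like(control))


# ---------------------------------------------------------------------------
# cortical thickness
# ---------------------------------------------------------------------------

def test_uniform_slab_thickness():
    mask = np.zeros((80, 6, 6), bool)
    mask[5:70] = True  # 65 voxels × 2 μm = 130 μm
    ct = cortical_thickness(mask, dz=2.0)
    assert ct.mean == pytest.approx(130.0)
    assert ct.range == 0.0


def test_wedge_range():
    nz, nx = 90, 78
    mask = np.zeros((nz, 1, nx), bool)
    for x in range(nx):
        n = int(round((77.0 + 77.0 * x / (nx - 1)) / 2.0))  # 77 → 154 μm
        mask[:n, 0, x] = True
    ct = cortical_thickness(mask, dz=2.0)
    assert ct.min == pytest.approx(77.0, abs=1.0)
    assert ct.max == pytest.approx(154.0, abs=1.0)
    assert ct.range == pytest.approx(77.0, abs=2.0)


def test_holey_column_reports_contiguous_span_and_flag():
    mask = np.zeros((20, 2, 2), bool)
    mask[2:12] = True
    mask[6, 0, 0] = False
    ct = cortical_thickness(mask, dz=2.0)
    assert bool(ct.holey_columns[0, 0])
    assert ct.thickness_map[0, 0] == pytest.approx(8.0)   # 4 voxels × 2 μm
    assert ct.thickness_map[1, 1] == pytest.approx(20.0)


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        cortical_thickness(np.zeros((4, 4, 4), bool), dz=2.0)
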