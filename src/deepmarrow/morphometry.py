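"""3D cell segmentation, volume/THG classification, colocalization gating and
cortical-thickness measurement.

Class gates follow the intravital B-lineage convention: segmented objects with
volume 65-500 μm³ are B cells (diameter 5-10 μm), 500-4189 μm³ plasma cells
(10-20 μm); 500 μm³ belongs to the plasma class and both outer bounds are
inclusive.  A cell is THG^hi when it contains at least ``min_voxels`` voxels
above the top-percentile threshold of the in-tissue THG intensity distribution
(strong THG defined as the highest signal appearing in 1% of voxels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core_io import ImageStack

B_GATE = (65.0, 500.0)
PLASMA_GATE = (500.0, 4189.0)


def sphere_volume(diameter_um: float) -> float:
    """Volume (μm³) of a sphere of the given diameter: d=20 μm → 4188.79 μm³."""
    return math.pi * diameter_um ** 3 / 6.0


@dataclass
class CellObject:
    """One segmented 3D object with per-channel statistics and class labels."""

    label: int
    volume: float                              # μm³
    centroid: tuple[float, float, float]       # (z, y, x) μm
    cell_class: Literal["B", "plasma", "excluded"] = "excluded"
    channel_mean: dict[str, float] = field(default_factory=dict)
    channel_max: dict[str, float] = field(default_factory=dict)
    thg_class: Literal["hi", "lo", "unset"] = "unset"
    thg_hi_voxels: int = 0
    coloc: dict[str, bool] = field(default_factory=dict)

    def as_record(self) -> dict:
        rec = {
            "label": self.label, "volume_um3": round(self.volume, 2),
            "z_um": round(self.centroid[0], 2), "y_um": round(self.centroid[1], 2),
            "x_um": round(self.centroid[2], 2), "class": self.cell_class,
            "thg_class": self.thg_class,
        }
        for ch, v in self.channel_mean.items():
            rec[f"mean_{ch}"] = round(v, 2)
        for ch, flag in self.coloc.items():
            rec[f"{ch}_positive"] = flag
        return rec


@dataclass
class ThgThreshold:
    percentile: float
    value: float
    channel: str

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _isotropic_copy(vol: np.ndarray, spacing: tuple[float, float, float],
                    iso_spacing: float | None) -> tuple[np.ndarray, float]:
    """Resample to cubic voxels.  The default target is the coarsest axis
    spacing (normally dz), which bounds the working-copy size; pass a finer
    ``iso_spacing`` to trade runtime for boundary accuracy."""
    target = iso_spacing or max(spacing)
    zoom = tuple(s / target for s in spacing)
    if all(abs(z - 1.0) < 1e-9 for z in zoom):
        return vol.astype(np.float32), target
    out = ndimage.zoom(vol.astype(np.float32), zoom, order=1)
    return out, target


def segment_cells(
    stack: ImageStack,
    channel: str,
    seed_diameter: float = 7.5,
    t: int = 0,
    iso_spacing: float | None = None,
    background_mode: Literal["gaussian", "median"] = "gaussian",
    min_volume: float = 20.0,
) -> tuple[np.ndarray, list[CellObject]]:
    """Segment cells in one fluorescence channel of one timepoint.

    Pipeline, on a cubic-voxel working copy: local-contrast background
    subtraction (a smoothed copy at 3x the seed diameter is subtracted),
    global Otsu threshold, 3D connected components, then a marker-based
    watershed split with markers at local maxima of the Euclidean distance
    transform spaced at least one seed diameter apart.  Volumes come from
    voxel counts x the working voxel volume; centroids are mapped back to μm.

    Returns the labelled working volume and the CellObject list (objects below
    ``min_volume`` μm³ are discarded as debris).  An empty foreground yields an
    empty list, not an error.
    """
    spacing = stack.spacing
    aniso = max(spacing) / min(spacing)
    if aniso > 10:
        raise ValueError(f"anisotropy ratio {aniso:.1f} > 10: refusing to segment")
    vol = stack.channel(channel)[t].astype(np.float32)
    work, vox = _isotropic_copy(vol, spacing, iso_spacing)

    bg_size = 3.0 * seed_diameter / vox
    if background_mode == "median":
        background = ndimage.median_filter(work, size=max(3, int(bg_size) | 1))
    else:
        background = ndimage.gaussian_filter(work, sigma=bg_size / 2.0)
    contrast = work - background

    finite = contrast[np.isfinite(contrast)]
    if finite.size == 0 or finite.max() <= finite.min():
        return np.zeros_like(work, dtype=np.int32), []
    # genuine signal always exceeds its local background, so the global
    # threshold is clamped at zero contrast
    thr = max(threshold_otsu(finite), 0.0)
    fg = contrast > thr
    if not fg.any():
        return np.zeros_like(work, dtype=np.int32), []

    dist = ndimage.distance_transform_edt(fg)
    # smoothing suppresses spurious distance-transform maxima that would split
    # single cells differently from frame to frame
    dist_s = ndimage.gaussian_filter(dist, sigma=1.0)
    # two seed points may sit one seed diameter apart (centre to centre)
    min_dist = max(1, int(seed_diameter / vox))
    peaks = peak_local_max(dist_s, min_distance=min_dist, labels=fg,
                           exclude_border=False)
    markers = np.zeros_like(work, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    # every connected component must carry at least one marker, or watershed
    # would silently drop it
    comp, n_comp = ndimage.label(fg)
    if n_comp:
        marked = set(np.unique(comp[markers > 0])) - {0}
        next_id = int(markers.max()) + 1
        for ci in range(1, n_comp + 1):
            if ci in marked:
                continue
            inside = comp == ci
            pos = np.unravel_index(np.argmax(np.where(inside, dist_s, -1.0)),
                                   comp.shape)
            markers[pos] = next_id
            next_id += 1
    if markers.max() == 0:
        labels, _ = ndimage.label(fg)
    else:
        labels = watershed(-dist_s, markers, mask=fg)

    vox_vol = vox ** 3
    cells: list[CellObject] = []
    for rp in regionprops(labels):
        v = rp.area * vox_vol
        if v < min_volume:
            labels[labels == rp.label] = 0
            continue
        centroid = tuple(c * vox for c in rp.centroid)
        cells.append(CellObject(label=int(rp.label), volume=float(v),
                                centroid=centroid))
    _attach_channel_stats(stack, labels, cells, t)
    return labels, cells


def labels_to_native(labels: np.ndarray, native_shape: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbour mapping of a working-grid label volume onto the native
    voxel grid, so per-cell statistics can be read off unresampled counts
    (resampling would dilute or miss single-voxel structures such as THG
    granules)."""
    if labels.shape == tuple(native_shape):
        return labels
    maps = [np.minimum((np.arange(n) * w) // n, w - 1).astype(np.intp)
            for n, w in zip(native_shape, labels.shape)]
    return labels[np.ix_(*maps)]


def _attach_channel_stats(stack: ImageStack, labels: np.ndarray,
                          cells: list[CellObject], t: int) -> None:
    """Per-channel mean/max inside each object, on the native grid."""
    if not cells:
        return
    ids = [c.label for c in cells]
    native = labels_to_native(labels, stack.shape_zyx)
    for ch in stack.channel_labels:
        chan = stack.channel(ch)[t].astype(np.float32)
        means = ndimage.mean(chan, labels=native, index=ids)
        maxs = ndimage.maximum(chan, labels=native, index=ids)
        for c, m, mx in zip(cells, means, maxs):
            c.channel_mean[ch] = float(m)
            c.channel_max[ch] = float(mx)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_by_volume(cells: Sequence[CellObject]) -> list[CellObject]:
    """Set the B/plasma/excluded class from the volume gates (in place)."""
    for c in cells:
        if B_GATE[0] <= c.volume < B_GATE[1]:
            c.cell_class = "B"
        elif PLASMA_GATE[0] <= c.volume <= PLASMA_GATE[1]:
            c.cell_class = "plasma"
        else:
            c.cell_class = "excluded"
    return list(cells)


def thg_threshold(stack: ImageStack, channel: str = "THG",
                  percentile: float = 99.0,
                  tissue_mask: np.ndarray | None = None,
                  t: int = 0) -> ThgThreshold:
    """Top-percentile THG intensity threshold over in-tissue voxels.

    ``tissue_mask`` restricts the distribution to tissue (default: all voxels,
    appropriate when the field of view is filled by marrow).
    """
    vol = stack.channel(channel)[t]
    vals = vol[tissue_mask] if tissue_mask is not None else vol.ravel()
    value = float(np.percentile(vals, percentile))
    return ThgThreshold(percentile=percentile, value=value, channel=channel)


def thg_hi_classify(
    stack: ImageStack,
    labels: np.ndarray,
    cells: Sequence[CellObject],
    channel: str = "THG",
    percentile: float = 99.0,
    min_voxels: int = 3,
    tissue_mask: np.ndarray | None = None,
    t: int = 0,
) -> ThgThreshold:
    """Set each cell's THG class from the top-percentile presence rule.

    A cell is THG^hi iff at least ``min_voxels`` of its *native-grid* voxels
    exceed the percentile threshold of the in-tissue THG distribution (the
    working-grid labels are mapped back to the native grid so that voxel-scale
    granule signal is never lost to resampling).  ``labels`` is the label
    volume returned by :func:`segment_cells`.
    """
    thr = thg_threshold(stack, channel, percentile, tissue_mask, t)
    chan = stack.channel(channel)[t].astype(np.float32)
    vals = chan[tissue_mask] if tissue_mask is not None else chan
    if float(np.max(vals)) == float(np.min(vals)):
        warnings.warn("constant THG channel: all cells classified THG^lo")
    native = labels_to_native(labels, stack.shape_zyx)
    above = chan > thr.value
    ids = [c.label for c in cells]
    if ids:
        counts = ndimage.sum_labels(above.astype(np.int64), labels=native, index=ids)
        for c, n in zip(cells, counts):
            c.thg_hi_voxels = int(n)
            c.thg_class = "hi" if n >= min_voxels else "lo"
    return thr


# ---------------------------------------------------------------------------
# Colocalization gating
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    detection_limit: float
    fraction_thg_hi_positive: float | None   # P(reference+ | THG^hi)
    fraction_positive_thg_hi: float | None   # P(THG^hi | reference+)
    n_thg_hi: int
    n_positive: int


def coloc_gate(
    stack: ImageStack,
    cells: Sequence[CellObject],
    reference_channel: str,
    control_mask: np.ndarray,
    t: int = 0,
) -> ColocResult:
    """Gate cells on a reference channel using a control-region detection limit.

    The detection limit is the highest reference-channel count inside the
    control region (an area where no genuine reference signal can occur, e.g.
    cortical bone for an ER tracker); a cell is reference-positive iff its mean
    in-cell reference signal exceeds that limit.  Returns both concordance
    fractions; a fraction is ``None`` when its denominator is empty.
    """
    if not np.any(control_mask):
        raise ValueError("empty control region")
    chan = stack.channel(reference_channel)[t]
    limit = float(chan[control_mask].max())
    n_hi = n_pos = n_hi_pos = 0
    for c in cells:
        positive = c.channel_mean.get(reference_channel, -math.inf) > limit
        c.coloc[reference_channel] = bool(positive)
        if c.thg_class == "hi":
            n_hi += 1
            n_hi_pos += positive
        n_pos += positive
    n_pos_hi = sum(1 for c in cells
                   if c.coloc.get(reference_channel) and c.thg_class == "hi")
    return ColocResult(
        detection_limit=limit,
        fraction_thg_hi_positive=(n_hi_pos / n_hi) if n_hi else None,
        fraction_positive_thg_hi=(n_pos_hi / n_pos) if n_pos else None,
        n_thg_hi=n_hi, n_positive=int(n_pos),
    )


# ---------------------------------------------------------------------------
# Cortical thickness
# ---------------------------------------------------------------------------

@dataclass
class CorticalThickness:
    thickness_map: np.ndarray       # (y, x) μm; NaN where the column is empty
    mean: float
    min: float
    max: float
    range: float
    holey_columns: np.ndarray       # (y, x) bool: interrupted z-span


def cortical_thickness(cortex_mask: np.ndarray, dz: float) -> CorticalThickness:
    """Per-column cortical thickness from a binary cortex mask.

    For every (x, y) column the thickness is dz x the length of the first
    contiguous run of mask voxels along z; columns whose mask is interrupted
    (a hole) report the contiguous span only and are flagged.
    """
    mask = np.asarray(cortex_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cortex mask")
    nz = mask.shape[0]
    counts = mask.sum(axis=0).astype(float)
    # first contiguous run per column
    first_true = np.argmax(mask, axis=0)
    padded = np.concatenate([mask, np.zeros((1,) + mask.shape[1:], dtype=bool)])
    run = np.zeros(mask.shape[1:], dtype=float)
    any_col = mask.any(axis=0)
    for y, x in zip(*np.nonzero(any_col)):
        k = first_true[y, x]
        while k < nz and mask[k, y, x]:
            k += 1
        run[y, x] = k - first_true[y, x]
    holey = any_col & (run < counts)
    thick = np.where(any_col, run * dz, np.nan)
    vals = thick[any_col]
    return CorticalThickness(
        thickness_map=thick, mean=float(np.mean(vals)), min=float(np.min(vals)),
        max=float(np.max(vals)), range=float(np.max(vals) - np.min(vals)),
        holey_columns=holey,
    )
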