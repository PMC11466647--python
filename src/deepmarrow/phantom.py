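"""Synthetic tibia phantom generator.

Produces seeded 3D and 3D+t stacks whose geometry, signal physics and cell
statistics emulate intravital deep-marrow three-photon data, together with the
ground truth needed to validate every downstream stage:

* a layered tissue (cortical bone over marrow) with per-layer effective
  attenuation lengths and exponential pulse-energy z-adaptation, entering the
  expected signal as ``[E(z)·exp(-Σ depth_i/l_e,i)]^n``;
* marrow cells of two volume classes (B cells 65-500 μm³, plasma cells
  500-4189 μm³) rendered as ellipsoids with uniform cytoplasmic fluorophore
  signal, a THG^lo membrane shell, and - in a configurable fraction of plasma
  cells - bright intracellular THG granules co-occurring with ER-channel signal;
* bright extracellular THG structures (vessel walls, erythrocytes, matrix
  interfaces) that populate the upper tail of the marrow THG histogram, which
  is what makes the top-1%-of-voxels THG^hi rule meaningful on real data;
* two-state cell motility with per-cell displacement rates drawn from a
  two-component Gaussian mixture truncated at zero;
* exponential photobleaching of fluorophore (never harmonic) channels and PMT
  noise (Poisson shot noise, Gaussian read noise, constant detector offset).

Attenuation is applied to the expected signal on the excitation side raised to
the excitation order; emission-path losses are folded into the same effective
``l_e``, mirroring how the attenuation length is defined operationally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .core_io import AcquisitionParams, ImageStack, seeded_rng
from .optics import TissueModel, ZAdaptation, z_adaptation

# Volume gates (μm³) defining the two B-lineage classes.
B_VOLUME_GATE = (65.0, 500.0)
PLASMA_VOLUME_GATE = (500.0, 4189.0)

REFERENCE_RATE_HZ = 3.0e6    # repetition rate the default brightnesses refer to
REFERENCE_DWELL_US = 1.98


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class CellPopulationSpec:
    """Cell counts, volumes and label-free/fluorescent signal statistics.

    ``thg_granule_fraction`` is the fraction of plasma cells bearing bright
    intracellular THG granules (the THG^hi phenotype); ``er_concordance`` the
    probability that a granule-bearing cell also carries ER-channel signal.
    Brightnesses are expected detector counts above offset at the reference
    repetition rate and dwell time.
    """

    n_b: int = 60
    n_plasma: int = 176
    b_volume_range: tuple[float, float] = B_VOLUME_GATE
    plasma_volume_range: tuple[float, float] = PLASMA_VOLUME_GATE
    thg_granule_fraction: float = 0.344
    er_concordance: float = 0.931
    fluorophore_brightness: float = 400.0
    er_brightness: float = 150.0
    granule_brightness: float = 600.0
    membrane_brightness_ratio: float = 0.2   # membrane THG^lo vs granule THG^hi
    granule_count_range: tuple[int, int] = (3, 8)
    granule_diameter_range: tuple[float, float] = (0.8, 1.5)  # μm
    struct_fraction: float = 0.02            # extracellular bright-THG voxels
    struct_brightness_range: tuple[float, float] = (0.4, 0.9)  # × granule
    max_axis_ratio: float = 1.5
    min_separation: float = 12.0             # μm between cell centres

    def __post_init__(self) -> None:
        for f in (self.thg_granule_fraction, self.er_concordance):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.b_volume_range[1] > PLASMA_VOLUME_GATE[0] + 1e-9:
            raise ValueError("B-cell volumes must not cross the 500 μm³ boundary")
        if self.plasma_volume_range[0] < B_VOLUME_GATE[1] - 1e-9:
            raise ValueError("plasma volumes must not cross the 500 μm³ boundary")


@dataclass
class MotilitySpec:
    """Two-state displacement-rate mixture (μm/min), truncated at zero.

    Defaults are the bimodal marrow plasma-cell statistics: a fast state with
    weight 0.378, mean 0.96 and s.d. 0.38, and a slow state with mean 0.21 and
    s.d. 0.12.  ``jitter_sd`` is the s.d. (μm) of the isotropic per-frame
    positional jitter superimposed on the constant-rate drift.
    """

    w_fast: float = 0.378
    mu_fast: float = 0.96
    sigma_fast: float = 0.38
    mu_slow: float = 0.21
    sigma_slow: float = 0.12
    jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_fast <= 1.0:
            raise ValueError("w_fast must lie in [0, 1]")
        if not self.mu_fast > self.mu_slow >= 0:
            raise ValueError("need mu_fast > mu_slow >= 0")
        if self.sigma_fast < 0 or self.sigma_slow < 0:
            raise ValueError("state s.d. must be non-negative")

    def draw_rate(self, state: str, rng: np.random.Generator) -> float:
        mu, sd = ((self.mu_fast, self.sigma_fast) if state == "fast"
                  else (self.mu_slow, self.sigma_slow))
        if sd == 0:
            return max(mu, 0.0)
        while True:  # truncation at zero by rejection
            v = rng.normal(mu, sd)
            if v >= 0:
                return v


@dataclass
class NoiseModel:
    """PMT noise: constant offset, Gaussian read noise, optional shot noise."""

    offset: float = 100.0
    read_sd: float = 2.0
    shot_noise: bool = True
    k_photobleach: float = 1.3e-3  # min⁻¹, applied to fluorophore channels

    def __post_init__(self) -> None:
        if self.offset < 0 or self.read_sd < 0 or self.k_photobleach < 0:
            raise ValueError("offset, read_sd and k_photobleach must be >= 0")

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        counts = rng.poisson(expected).astype(np.float32) if self.shot_noise \
            else expected.astype(np.float32)
        counts += self.offset
        if self.read_sd > 0:
            counts += rng.normal(0.0, self.read_sd, size=counts.shape).astype(np.float32)
        return np.clip(counts, 0.0, None)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    cell_id: int
    cell_class: Literal["B", "plasma"]
    volume: float                     # μm³
    centroid: tuple[float, float, float]  # (z, y, x) μm, FOV coordinates
    semi_axes: tuple[float, float, float]
    granule_bearing: bool
    er_positive: bool
    n_granules: int


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    control_mask: np.ndarray          # (z,y,x) bool, signal-free control region
    tissue_mask: np.ndarray           # (z,y,x) bool, in-tissue voxels
    cell_label_map: np.ndarray        # (z,y,x) int, 0 = background


@dataclass
class TrackTruth:
    cell: CellTruth
    state: Literal["fast", "slow"]
    rate: float                       # drawn displacement rate, μm/min
    positions: np.ndarray             # (frames, 3) (z,y,x) μm


@dataclass
class GroundTruthTracks:
    tracks: list[TrackTruth]
    dt: float                         # s
    control_mask: np.ndarray
    bleach_factors: np.ndarray        # per-frame fluorophore multiplier


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_axes(volume: float, max_ratio: float,
                    rng: np.random.Generator) -> tuple[float, float, float]:
    """Semi-axes (az, ay, ax) in μm with az smallest so cells fit a thin slab."""
    r1 = rng.uniform(1.0, max_ratio)
    r2 = rng.uniform(1.0, max_ratio)
    base = (3.0 * volume / (4.0 * math.pi * r1 * r2)) ** (1.0 / 3.0)
    axes = sorted([base, base * r1, base * r2])
    return axes[0], axes[1], axes[2]


def _sample_centres(n: int, semi_axes: list[tuple[float, float, float]],
                    extent: tuple[float, float, float], y_min: float,
                    min_sep: float, rng: np.random.Generator,
                    overlap_factor: float = 0.95) -> np.ndarray:
    """Rejection-sample non-interpenetrating cell centres.

    Cells are solid bodies: each pair must be separated by at least
    ``overlap_factor`` times the sum of their volume-equivalent radii (with
    ``min_sep`` as an absolute floor).
    """
    lz, ly, lx = extent
    radii = np.array([(az * ay * ax) ** (1.0 / 3.0) for az, ay, ax in semi_axes])
    placed: list[np.ndarray] = []
    factor = overlap_factor
    for i, (az, ay, ax) in enumerate(semi_axes):
        zlo, zhi = min(az, lz / 2), max(lz - az, lz / 2)
        req = np.maximum(min_sep, factor * (radii[i] + radii[:i])) if i else None
        for attempt in range(4000):
            p = np.array([rng.uniform(zlo, zhi),
                          rng.uniform(y_min + ay, ly - ay),
                          rng.uniform(ax, lx - ax)])
            if i == 0 or np.all(np.linalg.norm(np.array(placed) - p, axis=1) >= req):
                placed.append(p)
                break
            if attempt == 2000:  # relax if the packing is too tight
                factor *= 0.9
                req = np.maximum(min_sep, factor * (radii[i] + radii[:i]))
        else:
            raise RuntimeError("could not place cells; reduce counts or min_separation")
    return np.array(placed)


def _paint_ellipsoid(mask_out: np.ndarray, centre: np.ndarray,
                     axes: tuple[float, float, float],
                     spacing: tuple[float, float, float]) -> tuple[slice, ...]:
    """Set the ellipsoid's voxels to True in ``mask_out``; return its bbox."""
    lo = []
    hi = []
    for c, a, s, nvox in zip(centre, axes, spacing, mask_out.shape):
        lo.append(max(0, int(math.floor((c - a) / s)) - 1))
        hi.append(min(nvox, int(math.ceil((c + a) / s)) + 2))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    grids = np.ix_(*[np.arange(l, h) * s for (l, h), s in zip(zip(lo, hi), spacing)])
    dist = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, axes))
    mask_out[sl] |= dist <= 1.0
    return sl


# ---------------------------------------------------------------------------
# Depth scaling
# ---------------------------------------------------------------------------

def depth_factor(depths: np.ndarray, tissue: TissueModel | None,
                 law: ZAdaptation | None, order: int) -> np.ndarray:
    """Per-plane expected-signal factor [E(z)·exp(-optical depth)]^n, normalised
    to 1 at the shallowest plane."""
    if tissue is None and law is None:
        return np.ones_like(depths, dtype=float)
    e = np.asarray(law(depths), dtype=float) if law is not None else np.ones_like(depths)
    att = np.exp(-np.asarray(tissue.optical_depth(depths))) if tissue is not None \
        else np.ones_like(depths)
    f = (e * att) ** order
    return f / f[0]


def matched_z_adaptation(tissue: TissueModel, origin_z: float = 0.0) -> ZAdaptation:
    """The z-adaptation law that exactly compensates the tissue attenuation,
    yielding depth-flat expected signal (the goal of z-adaptation in practice)."""
    z0, z1 = origin_z, tissue.total_depth
    e0 = math.exp(float(tissue.optical_depth(z0)))
    e1 = math.exp(float(tissue.optical_depth(z1)))
    return z_adaptation([(z0, e0), (z1, e1)])


def _rate_scale(acq: AcquisitionParams | None) -> float:
    if acq is None:
        return 1.0
    return (acq.rep_rate * acq.dwell_time) / (REFERENCE_RATE_HZ * REFERENCE_DWELL_US)


# ---------------------------------------------------------------------------
# Marrow cell phantom (single timepoint)
# ---------------------------------------------------------------------------

DEFAULT_SHAPE = (11, 334, 334)
DEFAULT_SPACING = (3.0, 1.2, 1.2)


def _build_scene(shape, spacing, cells: CellPopulationSpec, rng,
                 control_band_um: float):
    """Place cells and extracellular THG structures; returns truth + paint data."""
    nz, ny, nx = shape
    dz, dy, dx = spacing
    extent = (nz * dz, ny * dy, nx * dx)

    classes = ["B"] * cells.n_b + ["plasma"] * cells.n_plasma
    volumes = np.concatenate([
        rng.uniform(*cells.b_volume_range, size=cells.n_b),
        rng.uniform(*cells.plasma_volume_range, size=cells.n_plasma),
    ]) if classes else np.empty(0)
    axes = [_ellipsoid_axes(v, cells.max_axis_ratio, rng) for v in volumes]
    centres = (_sample_centres(len(classes), axes, extent, control_band_um,
                               cells.min_separation, rng)
               if classes else np.empty((0, 3)))

    truth_cells: list[CellTruth] = []
    for i, cls in enumerate(classes):
        granule = bool(cls == "plasma" and rng.random() < cells.thg_granule_fraction)
        er = bool(granule and rng.random() < cells.er_concordance)
        n_gran = int(rng.integers(cells.granule_count_range[0],
                                  cells.granule_count_range[1] + 1)) if granule else 0
        truth_cells.append(CellTruth(
            cell_id=i + 1, cell_class=cls, volume=float(volumes[i]),
            centroid=tuple(centres[i]), semi_axes=axes[i],
            granule_bearing=granule, er_positive=er, n_granules=n_gran,
        ))
    return truth_cells


def generate_phantom(
    cells: CellPopulationSpec | None = None,
    tissue: TissueModel | None = None,
    acq: AcquisitionParams | None = None,
    noise: NoiseModel | None = None,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    origin_z: float = 300.0,
    applied_energy: ZAdaptation | Literal["matched"] | None = "matched",
    control_band_um: float = 18.0,
    channels: Sequence[str] = ("tdRFP", "THG", "ER"),
    seed: int | np.random.Generator | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Generate a single-timepoint marrow phantom with full ground truth.

    A band of width ``control_band_um`` along low y is kept free of cells and
    bright structures and serves as the signal-free control region used for
    detection-limit gating.  ``applied_energy="matched"`` (default) uses the
    z-adaptation law that compensates the tissue attenuation, as during
    acquisition; pass an explicit :class:`ZAdaptation` or ``None`` together
    with a tissue model to study uncompensated depth decay.
    """
    cells = cells or CellPopulationSpec()
    noise = noise or NoiseModel()
    rng = seeded_rng(seed)
    nz, ny, nx = shape
    dz, dy, dx = spacing

    if applied_energy == "matched":
        applied_energy = matched_z_adaptation(tissue, origin_z) if tissue else None

    truth_cells = _build_scene(shape, spacing, cells, rng, control_band_um)

    order = acq.excitation_order if acq else 3
    rate = _rate_scale(acq)
    expected = {ch: np.zeros(shape, dtype=np.float64) for ch in channels}
    occupancy = np.zeros(shape, dtype=bool)
    label_map = np.zeros(shape, dtype=np.int32)

    granule_b = cells.granule_brightness
    for ct in truth_cells:
        m = np.zeros(shape, dtype=bool)
        sl = _paint_ellipsoid(m, np.asarray(ct.centroid), ct.semi_axes, spacing)
        body = m[sl]
        occupancy[sl] |= body
        label_map[sl][body] = ct.cell_id
        if "tdRFP" in expected:
            expected["tdRFP"][sl][body] += cells.fluorophore_brightness
        if "ER" in expected and ct.er_positive:
            expected["ER"][sl][body] += cells.er_brightness
        if "THG" in expected:
            shell = body & ~ndimage.binary_erosion(body)
            expected["THG"][sl][shell] += cells.membrane_brightness_ratio * granule_b
            if ct.granule_bearing:
                _paint_granules(expected["THG"], ct, cells, spacing, rng)

    if "THG" in expected and cells.struct_fraction > 0:
        _paint_structures(expected["THG"], occupancy, cells, control_band_um,
                          spacing, rng)

    depths = origin_z + dz * np.arange(nz)
    factor = rate * depth_factor(depths, tissue, applied_energy, order)
    voxels = np.empty((1, len(channels), nz, ny, nx), dtype=np.float32)
    for ci, ch in enumerate(channels):
        exp_ch = expected[ch] * factor[:, None, None]
        voxels[0, ci] = noise.apply(exp_ch, rng)

    control = np.zeros(shape, dtype=bool)
    control[:, : int(control_band_um / dy), :] = True
    stack = ImageStack(voxels=voxels, spacing=spacing, channel_labels=list(channels),
                       origin_z=origin_z)
    gt = GroundTruth(cells=truth_cells, control_mask=control,
                     tissue_mask=np.ones(shape, dtype=bool), cell_label_map=label_map)
    return stack, gt


def _paint_granules(thg: np.ndarray, ct: CellTruth, cells: CellPopulationSpec,
                    spacing, rng) -> None:
    """Place each THG granule as a bright impulse in a distinct interior voxel.

    Granule diameters (0.8-1.5 μm) are below the axial voxel size, so granules
    are rendered as single-voxel impulses at full granule brightness.
    """
    taken: set[tuple[int, int, int]] = set()
    centre = np.asarray(ct.centroid)
    axes = np.asarray(ct.semi_axes)
    for _ in range(ct.n_granules):
        for _ in range(50):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = 0.6 * rng.random() ** (1 / 3)
            pos = centre + u * r * axes
            idx = tuple(int(round(p / s)) for p, s in zip(pos, spacing))
            if all(0 <= i < n for i, n in zip(idx, thg.shape)) and idx not in taken:
                taken.add(idx)
                thg[idx] += cells.granule_brightness
                break


def _paint_structures(thg: np.ndarray, occupancy: np.ndarray,
                      cells: CellPopulationSpec, control_band_um: float,
                      spacing, rng) -> None:
    """Scatter bright extracellular THG voxels over the marrow tissue."""
    dy = spacing[1]
    allowed = ~ndimage.binary_dilation(occupancy)
    allowed[:, : int(control_band_um / dy), :] = False
    idx = np.flatnonzero(allowed)
    n = int(round(cells.struct_fraction * thg.size))
    chosen = rng.choice(idx, size=min(n, idx.size), replace=False)
    lo, hi = cells.struct_brightness_range
    vals = rng.uniform(lo * cells.granule_brightness, hi * cells.granule_brightness,
                       size=chosen.size)
    np.add.at(thg.reshape(-1), chosen, vals)


# ---------------------------------------------------------------------------
# Time-lapse phantom
# ---------------------------------------------------------------------------

def generate_timelapse(
    cells: CellPopulationSpec | None = None,
    motility: MotilitySpec | None = None,
    frames: int = 21,
    dt: float = 60.0,
    tissue: TissueModel | None = None,
    acq: AcquisitionParams | None = None,
    noise: NoiseModel | None = None,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    origin_z: float = 300.0,
    applied_energy: ZAdaptation | Literal["matched"] | None = "matched",
    control_band_um: float = 0.0,
    channels: Sequence[str] = ("tdRFP",),
    seed: int | np.random.Generator | None = None,
) -> tuple[ImageStack, GroundTruthTracks]:
    """Generate a 3D+t marrow phantom with two-state cell motility.

    Each cell is assigned a motility state (fast with probability ``w_fast``)
    and a displacement rate drawn from that state's zero-truncated Gaussian;
    it then drifts at that constant rate along a fixed random in-plane
    direction with small isotropic Gaussian jitter, so the realized
    net-displacement/duration of every track equals the drawn rate up to
    jitter.  Fluorophore channels (not THG) are multiplied by
    ``exp(-k_photobleach · t)``.
    """
    if frames < 2:
        raise ValueError("need at least 2 frames")
    if dt <= 0:
        raise ValueError("dt must be positive")
    cells = cells or CellPopulationSpec()
    motility = motility or MotilitySpec()
    noise = noise or NoiseModel()
    rng = seeded_rng(seed)
    nz, ny, nx = shape
    dz, dy, dx = spacing

    if applied_energy == "matched":
        applied_energy = matched_z_adaptation(tissue, origin_z) if tissue else None

    truth_cells = _build_scene(shape, spacing, cells, rng, control_band_um)

    # motion: constant-rate in-plane drift + jitter
    tracks: list[TrackTruth] = []
    times_min = dt * np.arange(frames) / 60.0
    for ct in truth_cells:
        state = "fast" if rng.random() < motility.w_fast else "slow"
        rate = motility.draw_rate(state, rng)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([0.0, math.sin(theta), math.cos(theta)])
        pos = (np.asarray(ct.centroid)[None, :]
               + rate * times_min[:, None] * direction[None, :])
        if motility.jitter_sd > 0:
            pos = pos + rng.normal(0.0, motility.jitter_sd, size=pos.shape)
        tracks.append(TrackTruth(cell=ct, state=state, rate=rate, positions=pos))

    order = acq.excitation_order if acq else 3
    rate_sc = _rate_scale(acq)
    depths = origin_z + dz * np.arange(nz)
    factor = rate_sc * depth_factor(depths, tissue, applied_energy, order)
    bleach = np.exp(-noise.k_photobleach * times_min)

    # static extracellular THG structures, placed against the t=0 cell layout
    struct_field = None
    if "THG" in channels and cells.struct_fraction > 0:
        occ0 = np.zeros(shape, dtype=bool)
        for tr in tracks:
            _paint_ellipsoid(occ0, tr.positions[0], tr.cell.semi_axes, spacing)
        struct_field = np.zeros(shape, dtype=np.float64)
        _paint_structures(struct_field, occ0, cells, control_band_um, spacing, rng)

    voxels = np.empty((frames, len(channels), nz, ny, nx), dtype=np.float32)
    for t in range(frames):
        expected = {ch: np.zeros(shape, dtype=np.float64) for ch in channels}
        if struct_field is not None:
            expected["THG"] += struct_field
        occupancy = np.zeros(shape, dtype=bool)
        for tr in tracks:
            ct = tr.cell
            centre = tr.positions[t]
            # cells may drift out of the field of view; skip if fully outside
            if np.any(centre + np.asarray(ct.semi_axes) < 0) or \
               np.any(centre - np.asarray(ct.semi_axes) > np.array(shape) * np.array(spacing)):
                continue
            m = np.zeros(shape, dtype=bool)
            sl = _paint_ellipsoid(m, centre, ct.semi_axes, spacing)
            body = m[sl]
            occupancy[sl] |= body
            if "tdRFP" in expected:
                expected["tdRFP"][sl][body] += cells.fluorophore_brightness * bleach[t]
            if "ER" in expected and ct.er_positive:
                expected["ER"][sl][body] += cells.er_brightness * bleach[t]
            if "THG" in expected:
                shell = body & ~ndimage.binary_erosion(body)
                expected["THG"][sl][shell] += (cells.membrane_brightness_ratio
                                               * cells.granule_brightness)
                if ct.granule_bearing:
                    _paint_granules(expected["THG"], CellTruth(
                        ct.cell_id, ct.cell_class, ct.volume, tuple(centre),
                        ct.semi_axes, ct.granule_bearing, ct.er_positive,
                        ct.n_granules), cells, spacing, rng)
        for ci, ch in enumerate(channels):
            voxels[t, ci] = noise.apply(expected[ch] * factor[:, None, None], rng)

    control = np.zeros(shape, dtype=bool)
    if control_band_um > 0:
        control[:, : int(control_band_um / dy), :] = True
    stack = ImageStack(voxels=voxels, spacing=spacing, dt=dt,
                       channel_labels=list(channels), origin_z=origin_z)
    return stack, GroundTruthTracks(tracks=tracks, dt=dt, control_mask=control,
                                    bleach_factors=bleach)


# ---------------------------------------------------------------------------
# Homogeneous attenuation slab (calibration phantom)
# ---------------------------------------------------------------------------

def attenuation_slab(
    tissue: TissueModel,
    acq: AcquisitionParams | None = None,
    applied_energy: ZAdaptation | None = None,
    n_planes: int = 25,
    dz: float = 5.0,
    shape_yx: tuple[int, int] = (48, 96),
    signal_fraction_x: float = 0.6,
    brightness: float = 20000.0,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Homogeneous fluorescent slab for attenuation-length and SNR calibration.

    The left ``signal_fraction_x`` of every plane is filled with expected
    signal ``brightness · [E(z)·exp(-optical depth)]^n`` (normalised to
    ``brightness`` at the surface plane and scaled by repetition rate and
    dwell), the right margin carries only detector noise.  Returns
    ``(stack, signal_mask, background_mask)`` with per-plane (y,x) masks.
    """
    acq = acq or AcquisitionParams()
    noise = noise or NoiseModel()
    rng = seeded_rng(seed)
    ny, nx = shape_yx
    law = applied_energy or ZAdaptation.flat(acq.pulse_energy_surface)
    depths = dz * np.arange(n_planes)
    factor = _rate_scale(acq) * depth_factor(depths, tissue, law, acq.excitation_order)

    nx_sig = int(round(signal_fraction_x * nx))
    expected = np.zeros((n_planes, ny, nx))
    expected[:, :, :nx_sig] = brightness * factor[:, None, None]
    voxels = noise.apply(expected, rng)[None, None]
    stack = ImageStack(voxels=voxels, spacing=(dz, 1.0, 1.0),
                       channel_labels=["fluorophore"], origin_z=0.0)
    signal_mask = np.zeros((ny, nx), dtype=bool)
    signal_mask[:, :nx_sig] = True
    background_mask = np.zeros((ny, nx), dtype=bool)
    background_mask[:, nx_sig + 2:] = True
    return stack, signal_mask, background_mask


# ---------------------------------------------------------------------------
# Beads (resolution phantom) and mixed-pixel stacks (unmixing phantom)
# ---------------------------------------------------------------------------

def bead_stack(
    positions: Sequence[tuple[int, int, int]],
    sigma_um: tuple[float, float],
    shape: tuple[int, int, int] = (32, 64, 64),
    spacing: tuple[float, float, float] = (0.5, 0.1, 0.1),
    amplitude: float = 5000.0,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> ImageStack:
    """Sub-resolution beads blurred by a Gaussian focus: (axial, lateral) σ in μm."""
    rng = seeded_rng(seed)
    noise = noise or NoiseModel(shot_noise=False, read_sd=0.0, offset=0.0)
    expected = np.zeros(shape)
    for (z, y, x) in positions:
        expected[z, y, x] = amplitude
    sig_vox = (sigma_um[0] / spacing[0], sigma_um[1] / spacing[1],
               sigma_um[1] / spacing[2])
    expected = ndimage.gaussian_filter(expected, sig_vox)
    voxels = noise.apply(expected, rng)[None, None]
    return ImageStack(voxels=voxels, spacing=spacing, channel_labels=["THG"])


def generate_mixed_pixels(
    fingerprints: np.ndarray,
    abundances: np.ndarray,
    brightness: float = 1000.0,
    noise: NoiseModel | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    channel_labels: Sequence[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Build a multi-channel stack from fingerprint mixtures.

    ``fingerprints`` is (k, c); ``abundances`` is (k, z, y, x) with non-negative
    entries.  Each voxel's channel vector is the abundance-weighted fingerprint
    sum times ``brightness`` plus noise.  Returns the stack and the ground-truth
    component map (argmax abundance; -1 where all abundances are zero).
    """
    fp = np.asarray(fingerprints, dtype=float)
    ab = np.asarray(abundances, dtype=float)
    if np.any(ab < 0):
        raise ValueError("abundances must be non-negative")
    if ab.shape[0] != fp.shape[0]:
        raise ValueError("abundance components must match fingerprint count")
    noise = noise or NoiseModel(shot_noise=False, read_sd=0.0, offset=0.0)
    rng = seeded_rng(seed)
    k, c = fp.shape
    expected = brightness * np.einsum("kc,kzyx->czyx", fp, ab)
    voxels = np.stack([noise.apply(expected[i], rng) for i in range(c)])[None]
    labels = channel_labels or [f"ch{i}" for i in range(c)]
    component = np.where(ab.max(axis=0) > 0, ab.argmax(axis=0), -1)
    stack = ImageStack(voxels=voxels, spacing=spacing, channel_labels=labels)
    return stack, component
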