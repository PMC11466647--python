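"""Cell tracking, motility metrics, double-Gaussian motility decomposition and
temporal-difference flow maps.

Definitions (μm/min): the *mean displacement rate* of a track is its net
start-to-end displacement divided by the track duration — it separates sessile
from migratory cells; the *mean velocity* is the total path length divided by
the duration and is always at least the displacement rate (triangle
inequality).  The population displacement-rate histogram of marrow plasma
cells is decomposed into two Gaussian components whose areas give the fast and
slow subset weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.optimize import linear_sum_assignment

from .core_io import ImageStack, seeded_rng

_UNLINKABLE = 1.0e9


@dataclass
class Track:
    """Linked positions of one cell over time (frame gaps allowed)."""

    track_id: int
    frames: list[int]
    positions: np.ndarray            # (n, 3) (z, y, x) μm
    det_indices: list[int]           # per-frame detection index, for payload lookup
    cell_class: str = "unset"
    thg_class: str = "unset"
    duration: float | None = None            # min
    path_length: float | None = None         # μm
    net_displacement: float | None = None    # μm
    mean_velocity: float | None = None       # μm/min
    mean_displacement_rate: float | None = None  # μm/min

    @property
    def n_points(self) -> int:
        return len(self.frames)


def link_tracks(
    detections: Sequence[np.ndarray],
    max_dist: float = 8.0,
    max_gap: int = 3,
) -> list[Track]:
    """Link per-frame detections into tracks by optimal bipartite assignment.

    Frame-to-frame assignment minimizes the total linking distance between
    predicted track positions and detections (Hungarian algorithm), with a
    constant-velocity position predictor standing in for an autoregressive
    motion model.  A link is allowed only within ``max_dist`` μm per bridged
    frame: a track unmatched for g ≤ ``max_gap`` frames may reconnect within a
    distance budget of ``max_dist * (g + 1)``.  Deterministic given input order.

    ``detections[t]`` is an (n_t, 3) array of (z, y, x) centroids in μm;
    frames with zero detections are allowed.
    """
    if len(detections) < 2:
        raise ValueError("need at least 2 frames of detections")
    dets = [np.atleast_2d(np.asarray(d, dtype=float)).reshape(-1, 3)
            for d in detections]

    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for i, p in enumerate(dets[0]):
        tr = Track(track_id=len(tracks), frames=[0], positions=p[None, :],
                   det_indices=[i])
        tracks.append(tr)
        open_tracks.append(tr)

    for t in range(1, len(dets)):
        pts = dets[t]
        open_tracks = [tr for tr in open_tracks if t - tr.frames[-1] - 1 <= max_gap]
        if pts.size == 0:
            continue
        assigned = np.zeros(len(pts), dtype=bool)
        if open_tracks:
            cost = np.full((len(open_tracks), len(pts)), _UNLINKABLE)
            for i, tr in enumerate(open_tracks):
                gap = t - tr.frames[-1] - 1
                budget = max_dist * (gap + 1)
                pred = tr.positions[-1]
                if tr.n_points >= 2:
                    step = ((tr.positions[-1] - tr.positions[-2])
                            / (tr.frames[-1] - tr.frames[-2]))
                    pred = tr.positions[-1] + step * (gap + 1)
                d_pred = np.linalg.norm(pts - pred, axis=1)
                d_anchor = np.linalg.norm(pts - tr.positions[-1], axis=1)
                # hard frame-to-frame distance cap; predictor only ranks candidates
                ok = d_anchor <= budget
                cost[i, ok] = d_pred[ok]
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= _UNLINKABLE:
                    continue
                tr = open_tracks[r]
                tr.frames.append(t)
                tr.positions = np.vstack([tr.positions, pts[c]])
                tr.det_indices.append(int(c))
                assigned[c] = True
        for c in np.flatnonzero(~assigned):
            tr = Track(track_id=len(tracks), frames=[t], positions=pts[c][None, :],
                       det_indices=[int(c)])
            tracks.append(tr)
            open_tracks.append(tr)
    return tracks


def track_metrics(track: Track, dt: float) -> Track:
    """Populate duration, path length, net displacement and the two rates.

    ``dt`` is the frame interval in seconds.  Single-point tracks keep their
    metrics ``None`` (flagged undefined).
    """
    if track.n_points < 2:
        return track
    duration = (track.frames[-1] - track.frames[0]) * dt / 60.0
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    track.duration = duration
    track.path_length = float(steps.sum())
    track.net_displacement = float(
        np.linalg.norm(track.positions[-1] - track.positions[0]))
    track.mean_velocity = track.path_length / duration
    track.mean_displacement_rate = track.net_displacement / duration
    return track


def rose_plot_coordinates(tracks: Sequence[Track]) -> list[np.ndarray]:
    """Tracks translated to a common origin (rose-plot representation)."""
    return [tr.positions - tr.positions[0] for tr in tracks if tr.n_points >= 2]


# ---------------------------------------------------------------------------
# Double-Gaussian motility decomposition
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Two-component Gaussian decomposition of a displacement-rate histogram.

    Weights are component areas over the total area; the component with the
    larger mean is reported first (fast, slow) regardless of fit ordering.
    """

    weights: tuple[float, float]         # (w_fast, w_slow), sum to 1
    means: tuple[float, float]           # μm/min
    sds: tuple[float, float]
    n: int
    residual: float
    bin_edges: np.ndarray = field(repr=False)
    degenerate: bool = False


def _double_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def fit_displacement_mixture(
    rates: np.ndarray,
    bins: int = 20,
    min_cells: int = 30,
    n_starts: int = 5,
    fit_log_counts: bool = False,
    seed: int | np.random.Generator | None = 0,
) -> MixtureFit:
    """Fit the sum of two Gaussians to the histogram of per-cell rates.

    The rates are binned into ``bins`` equal-width bins over their range and
    the bin counts (or ``log(1+count)`` with ``fit_log_counts``, matching a
    logarithmic display) are fitted by least squares from an initialization at
    the 25th/75th-percentile split, refit from ``n_starts`` jittered starts
    with the best residual kept.  Component s.d. is floored at half the bin
    width.  Identical rates yield a flagged single-component fallback.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {rates.size}")
    if np.ptp(rates) == 0:
        edges = np.array([rates[0] - 0.5, rates[0] + 0.5])
        return MixtureFit(weights=(1.0, 0.0), means=(float(rates[0]),) * 2,
                          sds=(0.0, 0.0), n=rates.size, residual=0.0,
                          bin_edges=edges, degenerate=True)
    counts, edges = np.histogram(rates, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    y = np.log1p(counts) if fit_log_counts else counts.astype(float)
    bw = edges[1] - edges[0]
    s_floor = bw / 2.0

    q25, q75 = np.percentile(rates, [25, 75])
    # a component of a double *peak* decomposition must stay a peak: its spread
    # is capped well below the histogram range, or the fit degenerates into a
    # narrow spike plus a flat pedestal whose area swamps the weights
    s_cap = max(np.ptp(edges) / 3.0, 2.0 * s_floor)
    s0 = min(max(rates.std() / 2.0, s_floor), s_cap)
    a0 = max(y.max(), 1.0)
    p0 = np.array([a0, q25, s0, a0 / 2.0, q75, s0])
    lb = [0.0, edges[0] - bw, s_floor, 0.0, edges[0] - bw, s_floor]
    ub = [np.inf, edges[-1] + bw, s_cap, np.inf, edges[-1] + bw, s_cap]

    rng = seeded_rng(seed)
    best = None
    best_res = math.inf
    for i in range(n_starts):
        start = p0 if i == 0 else p0 * rng.uniform(0.7, 1.3, size=6)
        start = np.clip(start, lb, ub)
        try:
            popt, _ = optimize.curve_fit(_double_gauss, centers, y, p0=start,
                                         bounds=(lb, ub), maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        res = float(np.sum((y - _double_gauss(centers, *popt)) ** 2))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise RuntimeError(
            f"mixture fit did not converge from {n_starts} starts "
            f"(n={rates.size}, range=({edges[0]:.3g}, {edges[-1]:.3g}))")
    a1, mu1, sd1, a2, mu2, sd2 = best
    area1, area2 = a1 * sd1, a2 * sd2
    total = area1 + area2
    w1, w2 = (area1 / total, area2 / total) if total > 0 else (0.5, 0.5)
    comp = sorted(zip((mu1, mu2), (sd1, sd2), (w1, w2)), reverse=True)
    (mu_f, sd_f, w_f), (mu_s, sd_s, w_s) = comp
    return MixtureFit(weights=(w_f, w_s), means=(mu_f, mu_s), sds=(sd_f, sd_s),
                      n=int(rates.size), residual=best_res, bin_edges=edges)


# ---------------------------------------------------------------------------
# THG stratification
# ---------------------------------------------------------------------------

@dataclass
class ThgStratification:
    groups: dict[str, dict]
    empty_groups: list[str]


def stratify_by_thg(tracks: Sequence[Track],
                    mixture_min_cells: int = 30,
                    seed: int | np.random.Generator | None = 0) -> ThgStratification:
    """Group tracked cells by THG class and summarise each group's motility.

    Per group: mean, s.d. and n of mean displacement rates, plus a
    double-Gaussian mixture fit when the group is large enough (to contrast
    mono- vs bi-modal motility between THG^hi and THG^lo cells).
    """
    groups: dict[str, dict] = {}
    empty: list[str] = []
    for name in ("hi", "lo"):
        rates = np.array([tr.mean_displacement_rate for tr in tracks
                          if tr.thg_class == name
                          and tr.mean_displacement_rate is not None])
        if rates.size == 0:
            empty.append(name)
            groups[name] = {"n": 0, "mean": None, "sd": None, "mixture": None}
            continue
        fit = None
        if rates.size >= mixture_min_cells and np.ptp(rates) > 0:
            try:
                fit = fit_displacement_mixture(rates, min_cells=mixture_min_cells,
                                               seed=seed)
            except RuntimeError:
                fit = None
        groups[name] = {
            "n": int(rates.size), "mean": float(rates.mean()),
            "sd": float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
            "mixture": fit,
        }
    return ThgStratification(groups=groups, empty_groups=empty)


# ---------------------------------------------------------------------------
# Temporal-difference flow map
# ---------------------------------------------------------------------------

def _blue_to_red(u: float) -> tuple[float, float, float]:
    return (u, 0.15, 1.0 - u)


def flow_difference_map(
    stack: ImageStack,
    channel: str | None = None,
    colormap: Callable[[float], tuple[float, float, float]] = _blue_to_red,
) -> np.ndarray:
    """Colour-coded accumulation of consecutive-frame THG differences.

    For each pair of consecutive frames the absolute difference image is
    computed (z is max-projected first), coloured by its acquisition
    time-point, and all coloured differences are summed.  Static regions stay
    ~0; moving structures (e.g. flowing erythrocytes) leave a time-coloured
    trail.  Returns an (y, x, 3) RGB float image.
    """
    frames = stack.channel(channel) if channel else stack.voxels[:, 0]
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    proj = frames.max(axis=1).astype(float)  # (t, y, x)
    n_diff = proj.shape[0] - 1
    out = np.zeros(proj.shape[1:] + (3,), dtype=float)
    for t in range(1, proj.shape[0]):
        d = np.abs(proj[t] - proj[t - 1])
        u = (t - 1) / max(n_diff - 1, 1)
        out += d[:, :, None] * np.asarray(colormap(u))[None, None, :]
    return out
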