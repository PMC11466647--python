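"""Pixel-based similarity unmixing (SIMI) for low-channel multiphoton stacks.

SIMI is a classifier, not a linear unmixer: every above-background voxel is
assigned to the spectral fingerprint (possibly a *mixed*-component fingerprint
such as "THG+GFP+ER") that its normalized channel vector most resembles.
Fingerprints may come from separate single-colour reference measurements or be
identified *in situ* by clustering the normalized foreground vectors of the
multiplexed stack itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .core_io import ImageStack, seeded_rng


@dataclass
class Fingerprint:
    """Per-channel relative intensity signature, normalized to unit sum."""

    label: str
    vector: np.ndarray
    source: Literal["reference_measurement", "in_situ"] = "reference_measurement"

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if np.any(v < 0):
            raise ValueError("fingerprint vector must be non-negative")
        s = v.sum()
        if s <= 0:
            raise ValueError("fingerprint vector must not be all zero")
        self.vector = v / s


@dataclass
class ComponentMap:
    """Per-voxel fingerprint assignment.

    ``labels`` holds an index into ``fingerprint_labels`` (or -1 for
    background); ``score`` the similarity of each voxel to its assigned
    fingerprint, in [0, 1].
    """

    labels: np.ndarray
    score: np.ndarray
    fingerprint_labels: list[str]

    def label_image(self) -> np.ndarray:
        """String labels per voxel ('background' where unassigned)."""
        lut = np.array(["background"] + self.fingerprint_labels, dtype=object)
        return lut[self.labels + 1]


def _channel_vectors(stack: ImageStack, t: int = 0) -> np.ndarray:
    """(z·y·x, c) channel vectors of one timepoint."""
    v = stack.voxels[t].astype(float)
    return v.reshape(v.shape[0], -1).T


def default_background_threshold(stack: ImageStack, t: int = 0) -> float:
    """Otsu threshold on the channel-sum image (the default foreground rule)."""
    total = stack.voxels[t].astype(float).sum(axis=0)
    return float(threshold_otsu(total))


def identify_fingerprints(
    stack: ImageStack,
    k: int,
    background_threshold: float | None = None,
    seed: int | np.random.Generator | None = 0,
    labels: Sequence[str] | None = None,
) -> list[Fingerprint]:
    """Identify k in-situ fingerprints by clustering normalized foreground voxels.

    Above-background voxels (channel sum > threshold; Otsu on the channel-sum
    image by default) are normalized to unit sum and clustered with k-means
    (10 restarts, seeded).  Cluster centroids are returned as in-situ
    fingerprints, labelled by their dominant channel unless ``labels`` are
    supplied (ordered by descending cluster size).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if stack.n_channels < 2:
        raise ValueError("need at least 2 channels")
    vec = _channel_vectors(stack)
    thr = default_background_threshold(stack) if background_threshold is None \
        else background_threshold
    total = vec.sum(axis=1)
    fg = vec[total > thr]
    if fg.size == 0:
        raise ValueError("empty foreground: no voxel above the background threshold")
    norm = fg / fg.sum(axis=1, keepdims=True)
    if np.unique(np.round(norm, 12), axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct normalized vectors")
    rng = seeded_rng(seed)
    km = KMeans(n_clusters=k, n_init=10,
                random_state=int(rng.integers(2**31))).fit(norm)
    order = np.argsort(-np.bincount(km.labels_, minlength=k))
    chans = list(stack.channel_labels)
    out = []
    for rank, ci in enumerate(order):
        centroid = np.clip(km.cluster_centers_[ci], 0.0, None)  # numerical noise
        name = labels[rank] if labels is not None else chans[int(np.argmax(centroid))]
        out.append(Fingerprint(label=name, vector=centroid, source="in_situ"))
    return out


def cosine_similarity(vectors: np.ndarray, fingerprints: np.ndarray) -> np.ndarray:
    """(n, k) cosine similarities between voxel vectors and fingerprints."""
    vn = np.linalg.norm(vectors, axis=1, keepdims=True)
    fn = np.linalg.norm(fingerprints, axis=1, keepdims=True)
    sim = vectors @ fingerprints.T / np.where(vn > 0, vn, 1.0) / fn.T
    return np.clip(sim, 0.0, 1.0)


def simi_assign(
    stack: ImageStack,
    fingerprints: Sequence[Fingerprint],
    background_threshold: float | None = None,
    metric: Literal["cosine", "euclidean"] = "cosine",
) -> ComponentMap:
    """Assign every above-threshold voxel to its closest-matching fingerprint.

    The default match criterion is maximum cosine similarity between the
    voxel's channel vector and each unit-sum fingerprint (scale-free, so the
    assignment is invariant to per-voxel intensity); ``euclidean`` compares
    unit-sum-normalized voxel vectors by distance instead.  Ties break in
    fingerprint list order.  Below-threshold voxels are background (-1).
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    fp = np.stack([f.vector for f in fingerprints])
    vec = _channel_vectors(stack)
    thr = default_background_threshold(stack) if background_threshold is None \
        else background_threshold
    fg = vec.sum(axis=1) > thr

    labels = np.full(vec.shape[0], -1, dtype=np.int32)
    score = np.zeros(vec.shape[0], dtype=float)
    if fg.any():
        v = vec[fg]
        if metric == "cosine":
            sim = cosine_similarity(v, fp)
        else:
            norm = v / np.where(v.sum(axis=1, keepdims=True) > 0,
                                v.sum(axis=1, keepdims=True), 1.0)
            dist = np.linalg.norm(norm[:, None, :] - fp[None, :, :], axis=2)
            sim = 1.0 / (1.0 + dist)
        # argmax returns the first maximum: documented tie-break by list order
        best = sim.argmax(axis=1)
        labels[fg] = best
        score[fg] = sim[np.arange(len(best)), best]
    shape = stack.shape_zyx
    return ComponentMap(labels=labels.reshape(shape), score=score.reshape(shape),
                        fingerprint_labels=[f.label for f in fingerprints])
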