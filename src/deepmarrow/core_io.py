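"""Image-stack and table I/O shared by the whole analysis chain.

Stacks are multi-channel detector-count arrays with axis order ``(t, c, z, y, x)``;
``z`` index 0 is the shallowest plane and the physical depth of plane ``k`` is
``origin_z + k * dz`` (top-down intravital acquisition).  All physical quantities
are carried in the units of the underlying measurements: μm for lengths, nJ for
pulse energies, Hz for repetition rates, μm/min for motility.  Unit conversion
happens only at I/O boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("deepmarrow")

AXES = ("t", "c", "z", "y", "x")


class MetadataError(ValueError):
    """Sidecar metadata is missing or inconsistent with the voxel data."""


class FormatError(ValueError):
    """Voxel data shape contradicts the declared metadata."""


@dataclass
class ImageStack:
    """n-channel voxel array with physical spacing.

    Parameters
    ----------
    voxels
        Detector counts indexed ``(t, c, z, y, x)``.  Arrays with fewer axes are
        promoted on construction: ``(c, z, y, x)`` gains a singleton time axis and
        ``(z, y, x)`` gains both channel and time axes.
    spacing
        ``(dz, dy, dx)`` voxel spacing in μm, all strictly positive.
    dt
        Frame interval in seconds; ``None`` for single-timepoint stacks.
    channel_labels
        One name per channel, e.g. ``["THG", "tdRFP", "ER"]``.
    origin_z
        Depth (μm) of the first z-plane below the tissue surface.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_labels: Sequence[str]
    dt: float | None = None
    origin_z: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 3:
            v = v[None, None]
        elif v.ndim == 4:
            v = v[None]
        elif v.ndim != 5:
            raise FormatError(f"expected 3-5 axes, got {v.ndim}")
        self.voxels = v
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be 3 positive values, got {self.spacing}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != v.shape[1]:
            raise FormatError(
                f"{len(self.channel_labels)} channel labels for {v.shape[1]} channels"
            )
        if np.issubdtype(v.dtype, np.number) and v.size and v.min() < 0:
            raise FormatError("detector counts must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[2:]

    def channel(self, label: str) -> np.ndarray:
        """Return the ``(t, z, y, x)`` sub-array for a named channel."""
        try:
            i = list(self.channel_labels).index(label)
        except ValueError as exc:
            raise KeyError(f"no channel {label!r} in {list(self.channel_labels)}") from exc
        return self.voxels[:, i]

    def depths(self) -> np.ndarray:
        """Physical depth (μm) of every z-plane."""
        dz = self.spacing[0]
        return self.origin_z + dz * np.arange(self.voxels.shape[2])

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


@dataclass
class AcquisitionParams:
    """Laser and scan parameters of one acquisition.

    ``z_anchors`` are two ``(z μm, E nJ)`` pairs defining the exponential
    pulse-energy z-adaptation used during the scan; ``excitation_order`` is the
    number of photons absorbed per excitation event (2 or 3).
    """

    wavelength: float = 1650.0          # nm
    rep_rate: float = 3.0e6             # Hz
    pulse_energy_surface: float = 39.8  # nJ
    dwell_time: float = 1.98            # μs
    excitation_order: int = 3
    z_anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (50.0, 2.76),
        (488.0, 108.64),
    )

    def __post_init__(self) -> None:
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")
        if self.excitation_order not in (2, 3):
            raise ValueError("excitation_order must be 2 or 3")
        (z0, _), (z1, _) = self.z_anchors
        if z0 == z1:
            raise ValueError("z-adaptation anchor depths must be distinct")


# ---------------------------------------------------------------------------
# Stack I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a stack as a multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack",
                     metadata={"axes": "TCZYX"})
    meta = {
        "spacing_um": list(stack.spacing),
        "dt_s": stack.dt,
        "channels": list(stack.channel_labels),
        "origin_z_um": stack.origin_z,
    }
    with open(sidecar or sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Read a TIFF stack and its JSON sidecar, normalising axes to (t,c,z,y,x)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = Path(sidecar or sidecar_path(path))
    if not side.exists():
        raise MetadataError(f"missing sidecar {side}")
    with open(side) as fh:
        meta = json.load(fh)
    if "spacing_um" not in meta:
        raise MetadataError("sidecar lacks 'spacing_um'")
    if "channels" not in meta:
        raise MetadataError("sidecar lacks 'channels'")
    voxels = tifffile.imread(path)
    labels = meta["channels"]
    if voxels.ndim == 3:
        voxels = voxels[None, None]
    elif voxels.ndim == 4:
        # a 4-axis array is (c,z,y,x) if its first axis matches the channel count
        voxels = voxels[None] if voxels.shape[0] == len(labels) else voxels[:, None]
    if voxels.shape[1] != len(labels):
        raise FormatError(
            f"{voxels.shape[1]} channels in file, {len(labels)} labels in sidecar"
        )
    return ImageStack(
        voxels=voxels,
        spacing=tuple(meta["spacing_um"]),
        dt=meta.get("dt_s"),
        channel_labels=labels,
        origin_z=meta.get("origin_z_um", 0.0),
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Records passed to write_table do not share one key set."""


def write_table(records: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write keyed measurement records to CSV (dot-decimal, header always present).

    All records must share the same key set; an empty list yields a header-only
    file when the caller supplies no keys to infer, i.e. an empty CSV with no
    columns.
    """
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for r in records[1:]:
            if list(r.keys()) != keys:
                raise SchemaError(f"heterogeneous keys: {sorted(r)} vs {sorted(keys)}")
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False)
    return df


def seeded_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Canonical RNG construction: every randomized operation routes through this."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
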