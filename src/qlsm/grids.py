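"""Core in-memory containers for 3D microscopy volumes.

Axis convention throughout the package: arrays are indexed ``(z, y, x)``,
voxel indices are 0-based, and the physical position of a voxel center is
``index * spacing + origin`` in micrometres.  Lightsheet stacks are strongly
anisotropic (default 2.5 μm z step vs 1.3 μm in-plane), so every geometric
operation takes the physical spacing into account rather than working in
voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["VoxelGrid", "LabelVolume", "voxel_volume_um3", "OBJECT_TABLE_COLUMNS"]


def voxel_volume_um3(spacing_um: tuple[float, float, float]) -> float:
    """Physical volume of one voxel (dz * dy * dx), in μm³."""
    dz, dy, dx = spacing_um
    return float(dz) * float(dy) * float(dx)


@dataclass
class VoxelGrid:
    """One channel's 3D intensity array plus its physical geometry.

    Parameters
    ----------
    data:
        3D array, axis order (z, y, x).
    spacing_um:
        Physical voxel spacing (dz, dy, dx) in μm; all entries > 0.
    channel:
        Stain / channel name (e.g. ``"TUBB3"``, ``"CD31"``, ``"Emcn"``).
    origin_um:
        Physical position of voxel (0, 0, 0)'s center, in μm.  Non-zero
        after VOI cropping so physical coordinates are preserved.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel: str = ""
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_um}")
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return voxel_volume_um3(self.spacing_um)

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return replace(self, data=data, channel=self.channel if channel is None else channel)

    def index_to_um(self, index: np.ndarray) -> np.ndarray:
        """Convert (…, 3) voxel indices to physical μm coordinates."""
        return np.asarray(index, dtype=float) * np.array(self.spacing_um) + np.array(self.origin_um)

    def same_geometry(self, other: "VoxelGrid | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_um, other.spacing_um, atol=atol)
            and np.allclose(self.origin_um, other.origin_um, atol=atol)
        )


@dataclass
class LabelVolume:
    """Integer-labeled 3D objects sharing a :class:`VoxelGrid`'s geometry.

    Label 0 is background; labels ≥ 1 identify connected (or split)
    objects.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume_um3(self) -> float:
        return voxel_volume_um3(self.spacing_um)

    def mask(self) -> np.ndarray:
        return self.labels > 0


#: Columns of an object table (a plain :class:`pandas.DataFrame`): one row per
#: labeled object.  Downstream stages append ``phenotype``, ``compartment``,
#: ``region`` and per-phenotype shortest-distance columns as they run.
OBJECT_TABLE_COLUMNS = (
    "label",
    "n_voxels",
    "volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
)


def empty_object_table(extra: tuple[str, ...] = ()) -> pd.DataFrame:
    cols = list(OBJECT_TABLE_COLUMNS) + list(extra)
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols}).astype({"label": int, "n_voxels": int})
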