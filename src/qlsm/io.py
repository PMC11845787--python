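"""TIFF / OME-TIFF reading and writing with physical voxel spacing."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile

from .grids import VoxelGrid

__all__ = ["read_volume", "write_volume", "write_label_volume"]


def write_volume(grid: VoxelGrid, path) -> None:
    """Write one channel as OME-TIFF with PhysicalSizeX/Y/Z metadata (μm)."""
    path = Path(path)
    dz, dy, dx = grid.spacing_um
    metadata = {
        "axes": "ZYX",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
    }
    # photometric forced so small trailing dimensions are never taken as RGBA samples
    tifffile.imwrite(path, grid.data, ome=True, photometric="minisblack", metadata=metadata)


def _spacing_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is None:
        return None
    try:
        return (
            float(px.attrib["PhysicalSizeZ"]),
            float(px.attrib["PhysicalSizeY"]),
            float(px.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        return None


def read_volume(path, fallback_spacing_um: tuple[float, float, float] | None = None, channel: str = "") -> VoxelGrid:
    """Read a TIFF / OME-TIFF stack into a :class:`VoxelGrid`.

    Voxel spacing is taken from the OME PhysicalSize metadata; without it,
    ``fallback_spacing_um`` must be supplied.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(f"unsupported volume format: {path.suffix!r} (expected TIFF / OME-TIFF)")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _spacing_from_ome(tf.ome_metadata) if tf.ome_metadata else None
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"{path} does not contain a single-channel 3D stack (shape {data.shape})")
    if spacing is None:
        if fallback_spacing_um is None:
            raise ValueError(f"{path} carries no PhysicalSize metadata and no fallback spacing was given")
        spacing = fallback_spacing_um
    return VoxelGrid(data, spacing, channel=channel or path.stem)


def write_label_volume(labels: np.ndarray, spacing_um, path) -> None:
    """Write an integer label (or binary mask) volume as OME-TIFF."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    write_volume(VoxelGrid(arr, spacing_um, channel="labels"), path)
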