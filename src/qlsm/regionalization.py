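"""VOI cropping and periosteal / dural compartment assignment.

Analyses are run on fixed-size named volumes of interest (parietal bone,
coronal suture, frontal bone) whose dimensions are held constant across
samples.  Within a VOI, each nerve object is assigned to the periosteum
(outer, ectocranial side) or the dura mater (inner side) by its position
relative to a fitted mid-surface of the bone shell: a height map z(x, y)
estimated from a reference mask (bone or vasculature, which brackets the
shell) and smoothed in-plane.  The outer side is the -z side of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "VOISpec",
    "MidSurface",
    "crop_voi",
    "fit_mid_surface",
    "classify_compartment",
    "compartment_fractions",
]

VOI_NAMES = ("parietal", "coronal_suture", "frontal", "custom")


@dataclass
class VOISpec:
    """A named, axis-aligned VOI in physical μm.

    The voxel-center convention applies: the VOI is the half-open box
    ``[origin, origin + size)`` and a voxel belongs to it when its center
    does.
    """

    name: str
    origin_um: tuple[float, float, float]  # (z, y, x)
    size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.name not in VOI_NAMES:
            raise ValueError(f"VOI name must be one of {VOI_NAMES}, got {self.name!r}")
        self.origin_um = tuple(float(v) for v in self.origin_um)
        self.size_um = tuple(float(v) for v in self.size_um)
        if any(s <= 0 for s in self.size_um):
            raise ValueError("VOI size must be positive")


def voi_slices(grid: VoxelGrid, voi: VOISpec) -> tuple[slice, slice, slice]:
    sl = []
    for ax in range(3):
        sp = grid.spacing_um[ax]
        rel0 = voi.origin_um[ax] - grid.origin_um[ax]
        i0 = int(np.ceil(rel0 / sp - 1e-9))
        i1 = int(np.ceil((rel0 + voi.size_um[ax]) / sp - 1e-9))
        if i0 < 0 or i1 > grid.shape[ax]:
            raise ValueError(
                f"VOI {voi.name!r} exceeds the volume along axis {ax}: voxels [{i0}, {i1}) of {grid.shape[ax]}"
            )
        sl.append(slice(i0, i1))
    return tuple(sl)


def crop_voi(grid: VoxelGrid, voi: VOISpec) -> VoxelGrid:
    """Crop a VOI, preserving physical coordinates via the origin offset."""
    sl = voi_slices(grid, voi)
    new_origin = tuple(
        grid.origin_um[ax] + sl[ax].start * grid.spacing_um[ax] for ax in range(3)
    )
    return VoxelGrid(grid.data[sl].copy(), grid.spacing_um, channel=grid.channel, origin_um=new_origin)


@dataclass
class MidSurface:
    """Bone-shell mid-plane as a height map z(y, x) in μm (stack coords)."""

    height_um: np.ndarray  # (ny, nx)
    spacing_yx_um: tuple[float, float]
    origin_um: tuple[float, float, float]
    coverage: float = 1.0
    fit_residual_um: float = 0.0

    def height_at(self, y_um: np.ndarray, x_um: np.ndarray) -> np.ndarray:
        """Nearest-column lookup of the surface height at physical (y, x)."""
        dy, dx = self.spacing_yx_um
        iy = np.clip(np.rint((np.asarray(y_um) - self.origin_um[1]) / dy).astype(int), 0, self.height_um.shape[0] - 1)
        ix = np.clip(np.rint((np.asarray(x_um) - self.origin_um[2]) / dx).astype(int), 0, self.height_um.shape[1] - 1)
        return self.height_um[iy, ix]


def fit_mid_surface(
    reference: VoxelGrid,
    smooth_sigma_um: float = 10.0,
    min_coverage: float = 0.5,
) -> MidSurface:
    """Fit the shell mid-surface from a reference mask.

    Per (y, x) column the raw height is the midpoint between the first and
    last reference voxel along z; empty columns are filled from their
    nearest populated column and the map is low-pass filtered in-plane.
    The reference must cover at least ``min_coverage`` of the footprint.
    """
    mask = np.asarray(reference.data, dtype=bool)
    nz = mask.shape[0]
    any_col = mask.any(axis=0)
    coverage = float(any_col.mean())
    if coverage < min_coverage:
        raise ValueError(
            f"reference mask covers only {coverage:.1%} of the footprint (need >= {min_coverage:.0%})"
        )
    zidx = np.arange(nz)[:, None, None]
    first = np.where(mask, zidx, nz).min(axis=0).astype(float)
    last = np.where(mask, zidx, -1).max(axis=0).astype(float)
    mid_vox = (first + last) / 2.0

    # For a shell-bracketing reference (e.g. vasculature lining both bone
    # faces) a column that sees only one face puts the "midpoint" inside
    # that face.  When column extents are clearly bimodal, trust only the
    # columns spanning both faces and fill the rest from their neighbors.
    extent = last - first
    ext_cov = extent[any_col]
    trusted = any_col.copy()
    if ext_cov.size and (ext_cov.max() - ext_cov.min()) > 4:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(ext_cov)
        candidate = any_col & (extent >= thr)
        if candidate.mean() >= 0.05:
            trusted = candidate

    if not trusted.all():
        # nearest-trusted-column fill
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~trusted, sampling=reference.spacing_um[1:], return_indices=True
        )
        mid_vox = mid_vox[iy, ix]

    height = mid_vox * reference.spacing_um[0] + reference.origin_um[0]
    sigma_vox = (smooth_sigma_um / reference.spacing_um[1], smooth_sigma_um / reference.spacing_um[2])
    smoothed = ndimage.gaussian_filter(height, sigma_vox, mode="nearest")
    residual = float(np.sqrt(np.mean((smoothed[trusted] - height[trusted]) ** 2)))
    return MidSurface(
        height_um=smoothed,
        spacing_yx_um=(reference.spacing_um[1], reference.spacing_um[2]),
        origin_um=reference.origin_um,
        coverage=coverage,
        fit_residual_um=residual,
    )


def classify_compartment(objects: pd.DataFrame, surface: MidSurface) -> pd.DataFrame:
    """Assign each object to the periosteum or dura mater.

    An object whose centroid lies on the outer (-z, ectocranial) side of
    the mid-surface is periosteal, the inner side dural; a centroid exactly
    on the surface counts as periosteal.  The signed distance to the
    surface (positive toward the outside) is stored.  Objects over an
    undefined surface column are flagged ``unassigned``.
    """
    out = objects.copy()
    if len(out) == 0:
        out["compartment"] = pd.Series(dtype=object)
        out["surface_signed_dist_um"] = pd.Series(dtype=float)
        return out
    z = out["centroid_z_um"].to_numpy(dtype=float)
    h = np.asarray(
        surface.height_at(out["centroid_y_um"].to_numpy(dtype=float), out["centroid_x_um"].to_numpy(dtype=float)),
        dtype=float,
    )
    signed = h - z  # positive: centroid above the surface, i.e. outer side
    comp = np.where(signed >= 0.0, "periosteal", "dural").astype(object)
    comp[~np.isfinite(signed)] = "unassigned"
    out["compartment"] = comp
    out["surface_signed_dist_um"] = signed
    return out


def compartment_fractions(objects: pd.DataFrame, compartment_volumes_um3: dict | None = None) -> dict:
    """Count-based periosteal/dural fractions (over assigned objects) plus,
    when compartment volumes are supplied, per-compartment volume densities.

    The nerve section count in each compartment is normalized by the total
    assigned count; unassigned objects are reported separately and excluded
    from the normalization.
    """
    if len(objects) == 0:
        raise ValueError("no objects: compartment fractions undefined")
    comp = objects["compartment"]
    n_peri = int((comp == "periosteal").sum())
    n_dura = int((comp == "dural").sum())
    n_un = int((comp == "unassigned").sum())
    n_assigned = n_peri + n_dura
    if n_assigned == 0:
        raise ValueError("no assigned objects: compartment fractions undefined")
    result = {
        "periosteal_fraction": n_peri / n_assigned,
        "dural_fraction": n_dura / n_assigned,
        "n_periosteal": n_peri,
        "n_dural": n_dura,
        "n_unassigned": n_un,
    }
    if "volume_um3" in objects.columns:
        v_peri = float(objects.loc[comp == "periosteal", "volume_um3"].sum())
        v_dura = float(objects.loc[comp == "dural", "volume_um3"].sum())
        if v_peri + v_dura > 0:
            # volume-weighted variant: robust to unequal split-object sizes
            result["periosteal_volume_fraction"] = v_peri / (v_peri + v_dura)
            result["dural_volume_fraction"] = v_dura / (v_peri + v_dura)
    if compartment_volumes_um3 is not None:
        for name, key in (("periosteal", "periosteal"), ("dural", "dural")):
            vol = float(objects.loc[comp == name, "volume_um3"].sum())
            region = float(compartment_volumes_um3[key])
            result[f"{name}_volume_density"] = vol / region if region > 0 else float("nan")
    return result
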