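"""Vessel phenotype classification from CD31 / Emcn binary masks.

The three quantified phenotypes are CD31hiEmcn- (P1, arteriole-like),
CD31hiEmcnhi (P2, "type H") and CD31loEmcnhi (P3).  Classification follows
binary-mask logic on down-sampled data: objects of the CD31hi mask are P2
when masked Emcn signal is present inside them and P1 when it is absent;
objects of the Emcnhi mask are P3 unless they co-localize with CD31hi
signal (in which case they were already counted through the CD31 mask).
The CD31loEmcnlo ("type L") sinusoidal phenotype is not quantified.

Masks are first split into ~10 μm objects by seeded watershed so that the
phenotype and spatial statistics operate on locally uniform pieces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from .grids import LabelVolume, voxel_volume_um3

__all__ = [
    "PhenotypeRuleSet",
    "downsample",
    "split_objects",
    "classify_phenotype",
    "phenotype_fractions",
]

PHENOTYPE_CODES = ("P1", "P2", "P3")


@dataclass
class PhenotypeRuleSet:
    """Thresholds and overlap rule for phenotype calls.

    ``overlap_min_voxels`` is the number of masked voxels of the other
    stain that must fall inside an object to count as "presence" (default
    1, i.e. plain presence/absence).
    """

    cd31_hi_threshold: float = 100.0
    emcn_hi_threshold: float = 100.0
    overlap_min_voxels: int = 1

    def __post_init__(self) -> None:
        if self.overlap_min_voxels < 1:
            raise ValueError("overlap_min_voxels must be >= 1")


def downsample(volume: np.ndarray, factor: int = 2) -> np.ndarray:
    """Mean-pool over ``factor``³ blocks; output shape is ceil(shape/factor).

    Boundary blocks are padded by edge replication so partial blocks average
    their available voxels.  Boolean input is returned as the block mean in
    [0, 1] (threshold at 0.5 to recover a mask); physical spacing of the
    result is the input spacing times ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vol = np.asarray(volume)
    if factor == 1:
        return vol.astype(np.float32) if vol.dtype == bool else vol.copy()
    pad = [(0, (-s) % factor) for s in vol.shape]
    v = np.pad(vol.astype(np.float32), pad, mode="edge")
    nz, ny, nx = (s // factor for s in v.shape)
    v = v.reshape(nz, factor, ny, factor, nx, factor)
    return v.mean(axis=(1, 3, 5))


def downsample_mask(mask: np.ndarray, factor: int = 2) -> np.ndarray:
    return downsample(np.asarray(mask, dtype=bool), factor) >= 0.5


def split_objects(
    mask: np.ndarray,
    spacing_um: tuple[float, float, float],
    seed_diameter_um: float = 10.0,
) -> LabelVolume:
    """Split a binary mask into ~``seed_diameter_um`` objects.

    Seeded watershed on the interior anisotropic distance transform: seed
    candidates are local maxima of the distance map, accepted greedily in
    order of decreasing depth (ties broken by lexicographic voxel order)
    subject to a mutual physical spacing >= ``seed_diameter_um``.  Any
    connected component left without a seed receives one at its deepest
    voxel, so the union of the split labels reproduces the input mask
    exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    lv_empty = LabelVolume(np.zeros(mask.shape, dtype=np.int32), spacing_um)
    if not mask.any():
        return lv_empty
    sp = np.asarray(spacing_um)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing_um)

    # Poisson-disk seed placement over every mask voxel, deepest first:
    # guarantees each voxel lies within the seed spacing of some seed, so
    # thin or bundled tubes are still cut at the ~seed_diameter scale
    cand = np.argwhere(mask)
    depth = edt[tuple(cand.T)]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -depth))
    cand = cand[order]
    cand_um = cand * sp
    tree = cKDTree(cand_um)
    suppressed = np.zeros(len(cand), dtype=bool)
    seeds = []
    for i in range(len(cand)):
        if suppressed[i]:
            continue
        seeds.append(cand[i])
        suppressed[tree.query_ball_point(cand_um[i], seed_diameter_um)] = True
    seeds = np.asarray(seeds)

    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)

    # make sure every 26-connected component carries at least one marker
    comp, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    has_seed = np.zeros(n_comp + 1, dtype=bool)
    has_seed[comp[tuple(seeds.T)]] = True
    next_label = len(seeds) + 1
    for c in np.nonzero(~has_seed[1:])[0] + 1:
        sub = comp == c
        flat = np.flatnonzero(sub.ravel())
        best = flat[np.argmax(edt.ravel()[flat])]
        markers.ravel()[best] = next_label
        next_label += 1

    labels = watershed(-edt, markers=markers, mask=mask)
    return LabelVolume(labels.astype(np.int32), spacing_um)


def _overlap_counts(labels: np.ndarray, other_mask: np.ndarray, n: int) -> np.ndarray:
    """Voxels of ``other_mask`` inside each label (index 0 unused)."""
    return np.bincount(labels.ravel(), weights=other_mask.ravel().astype(np.float64), minlength=n + 1).astype(int)


def classify_phenotype(
    cd31_objects: LabelVolume,
    emcn_objects: LabelVolume,
    rules: PhenotypeRuleSet | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign P1/P2/P3 phenotypes to split vessel objects.

    Returns the per-object table (label, source mask, phenotype, volume)
    and a voxel phenotype map (0 background, 1=P1, 2=P2, 3=P3) that
    partitions the union of the two masks exactly: CD31hi objects become P1
    or P2 by absence/presence of Emcnhi signal; Emcnhi voxels not already
    covered become P3 if their object is free of CD31hi signal, otherwise
    they join P2 (that vessel is already counted through the CD31 mask).
    """
    rules = PhenotypeRuleSet() if rules is None else rules
    if cd31_objects.shape != emcn_objects.shape:
        raise ValueError("CD31 and Emcn label volumes have different shapes")
    if not np.allclose(cd31_objects.spacing_um, emcn_objects.spacing_um):
        raise ValueError("CD31 and Emcn label volumes have different spacing")
    cd31_lab = cd31_objects.labels
    emcn_lab = emcn_objects.labels
    cd31_mask = cd31_lab > 0
    emcn_mask = emcn_lab > 0
    voxvol = cd31_objects.voxel_volume_um3

    n_c = cd31_objects.n_objects
    n_e = emcn_objects.n_objects
    emcn_in_cd31 = _overlap_counts(cd31_lab, emcn_mask, n_c)
    cd31_in_emcn = _overlap_counts(emcn_lab, cd31_mask, n_e)
    counts_c = np.bincount(cd31_lab.ravel(), minlength=n_c + 1)
    counts_e = np.bincount(emcn_lab.ravel(), minlength=n_e + 1)

    cd31_is_p2 = emcn_in_cd31 >= rules.overlap_min_voxels  # presence of masked Emcn
    emcn_is_p3 = cd31_in_emcn < rules.overlap_min_voxels  # no co-localized CD31

    phen_map = np.zeros(cd31_lab.shape, dtype=np.uint8)
    lut_c = np.where(cd31_is_p2, 2, 1).astype(np.uint8)
    lut_c[0] = 0
    phen_map[cd31_mask] = lut_c[cd31_lab[cd31_mask]]
    lut_e = np.where(emcn_is_p3, 3, 2).astype(np.uint8)
    lut_e[0] = 0
    free = emcn_mask & ~cd31_mask
    phen_map[free] = lut_e[emcn_lab[free]]

    rows = []
    sp = np.asarray(cd31_objects.spacing_um)
    if n_c:
        cent = np.asarray(ndimage.center_of_mass(cd31_mask, cd31_lab, np.arange(1, n_c + 1)), dtype=float)
        for i in range(1, n_c + 1):
            rows.append(
                {
                    "label": i,
                    "source": "cd31",
                    "phenotype": "P2" if cd31_is_p2[i] else "P1",
                    "n_voxels": int(counts_c[i]),
                    "volume_um3": counts_c[i] * voxvol,
                    "centroid_z_um": cent[i - 1, 0] * sp[0],
                    "centroid_y_um": cent[i - 1, 1] * sp[1],
                    "centroid_x_um": cent[i - 1, 2] * sp[2],
                }
            )
    if n_e:
        cent = np.asarray(ndimage.center_of_mass(emcn_mask, emcn_lab, np.arange(1, n_e + 1)), dtype=float)
        for i in range(1, n_e + 1):
            if not emcn_is_p3[i]:
                continue  # co-localized with CD31hi: dropped, counted via CD31 mask
            rows.append(
                {
                    "label": i,
                    "source": "emcn",
                    "phenotype": "P3",
                    "n_voxels": int(counts_e[i]),
                    "volume_um3": counts_e[i] * voxvol,
                    "centroid_z_um": cent[i - 1, 0] * sp[0],
                    "centroid_y_um": cent[i - 1, 1] * sp[1],
                    "centroid_x_um": cent[i - 1, 2] * sp[2],
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "label",
            "source",
            "phenotype",
            "n_voxels",
            "volume_um3",
            "centroid_z_um",
            "centroid_y_um",
            "centroid_x_um",
        ],
    )
    return table, phen_map


def phenotype_fractions(phen_map: np.ndarray, spacing_um: tuple[float, float, float]) -> dict:
    """Per-phenotype volume fraction, normalized by the overall vessel
    volume (the CD31hi ∪ Emcnhi union, which the phenotype map partitions).

    Returns ``{"P1": f1, "P2": f2, "P3": f3, "overall_vessel_volume_um3": V}``.
    Raises if the overall vessel volume is zero (fractions undefined).
    """
    phen_map = np.asarray(phen_map)
    counts = np.bincount(phen_map.ravel(), minlength=4)
    union = int(counts[1:4].sum())
    if union == 0:
        raise ValueError("overall vessel volume is zero; phenotype fractions undefined")
    voxvol = voxel_volume_um3(spacing_um)
    out = {code: counts[k] / union for k, code in enumerate(PHENOTYPE_CODES, start=1)}
    out["overall_vessel_volume_um3"] = union * voxvol
    return out
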