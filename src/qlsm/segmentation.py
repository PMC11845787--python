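"""Pixel classification and mask generation.

Two segmentation routes mirror how the imaging study treated its stains:

* nerve channels go through a trainable random-forest pixel classifier on a
  multi-scale feature stack (intensity, gradient, Laplacian, Hessian and
  structure-tensor eigenvalues), the open-source equivalent of an
  interactive pixel-classification workflow;
* vessel channels use grayscale background subtraction (10 μm structuring
  radius) followed by an absolute intensity threshold.

Both routes end in connected-component labeling and a 10⁴ μm³ volume filter
that removes subcellular-sized fragments.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import hessian_matrix, structure_tensor
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .grids import LabelVolume, VoxelGrid, empty_object_table, voxel_volume_um3

__all__ = [
    "DEFAULT_FEATURE_SCALES",
    "FeatureStack",
    "PixelClassifierModel",
    "extract_features",
    "train_pixel_classifier",
    "predict_mask",
    "threshold_absolute",
    "subtract_background",
    "label_components",
    "filter_by_volume",
    "mask_from_table",
    "sample_training_labels",
]

#: Default feature scales, in units of in-plane (x-y) voxels.
DEFAULT_FEATURE_SCALES = (0.7, 1.0, 1.6, 3.5, 5.0, 10.0)

_FEATURE_KINDS = ("gaussian", "gradient", "laplacian", "hessian", "structure")


def _sym3_eigvals(elems) -> list[np.ndarray]:
    """Eigenvalues of a field of symmetric 3x3 matrices, descending.

    Vectorized trigonometric closed form (no per-voxel LAPACK calls);
    ``elems`` is the upper-triangle sequence (a11, a12, a13, a22, a23, a33)
    as produced by skimage's ``hessian_matrix`` / ``structure_tensor``.
    """
    a11, a12, a13, a22, a23, a33 = (np.asarray(e, dtype=np.float64) for e in elems)
    q = (a11 + a22 + a33) / 3.0
    p1 = a12**2 + a13**2 + a23**2
    p2 = (a11 - q) ** 2 + (a22 - q) ** 2 + (a33 - q) ** 2 + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    safe_p = np.where(p > 0, p, 1.0)
    b11, b22, b33 = (a11 - q) / safe_p, (a22 - q) / safe_p, (a33 - q) / safe_p
    b12, b13, b23 = a12 / safe_p, a13 / safe_p, a23 / safe_p
    detb = (
        b11 * (b22 * b33 - b23**2)
        - b12 * (b12 * b33 - b23 * b13)
        + b13 * (b12 * b23 - b22 * b13)
    )
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    zero = p == 0
    if zero.any():
        for e in (e1, e2, e3):
            e[zero] = q[zero]
    return [e1.astype(np.float32), e2.astype(np.float32), e3.astype(np.float32)]


def _sigma_vox(scale: float, spacing_um: tuple[float, float, float]) -> tuple[float, float, float]:
    """Scale is expressed in x-y voxels; the z sigma is shrunk by the
    spacing ratio so smoothing is isotropic in physical μm."""
    dz, dy, dx = spacing_um
    ref = min(dy, dx)
    return (scale * ref / dz, scale * ref / dy, scale * ref / dx)


@dataclass
class FeatureStack:
    """Per-voxel feature vectors: shape (n_features, z, y, x)."""

    data: np.ndarray
    names: list[str]
    scales: tuple[float, ...]
    spacing_um: tuple[float, float, float]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def flat(self) -> np.ndarray:
        """(n_voxels, n_features) view for the classifier."""
        return self.data.reshape(self.n_features, -1).T


def extract_features(
    channel: VoxelGrid,
    scales: tuple[float, ...] = DEFAULT_FEATURE_SCALES,
    kinds: tuple[str, ...] = _FEATURE_KINDS,
    truncate: float = 4.0,
) -> FeatureStack:
    """Compute the multi-scale feature stack for pixel classification.

    Features per scale: Gaussian-smoothed intensity, Gaussian gradient
    magnitude, Laplacian of Gaussian, the three Hessian eigenvalues and the
    three structure-tensor eigenvalues — intensity, edge, blob/ridge and
    texture descriptors respectively.  Smoothing is anisotropy-aware (see
    :func:`_sigma_vox`).
    """
    img = np.asarray(channel.data, dtype=np.float32)
    if not np.isfinite(img).all():
        raise ValueError("channel contains non-finite values")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    unknown = set(kinds) - set(_FEATURE_KINDS)
    if unknown:
        raise ValueError(f"unknown feature kinds: {sorted(unknown)}")

    feats: list[np.ndarray] = []
    names: list[str] = []
    for s in scales:
        sigma = _sigma_vox(s, channel.spacing_um)
        if "gaussian" in kinds:
            feats.append(ndimage.gaussian_filter(img, sigma, truncate=truncate))
            names.append(f"gaussian_s{s}")
        if "gradient" in kinds:
            feats.append(ndimage.gaussian_gradient_magnitude(img, sigma, truncate=truncate))
            names.append(f"gradient_s{s}")
        if "laplacian" in kinds:
            # discrete Laplacian of the smoothed image: exactly zero on
            # constants even at sub-voxel sigma, where the truncated
            # Gaussian-derivative kernel is not
            feats.append(ndimage.laplace(ndimage.gaussian_filter(img, sigma, truncate=truncate), mode="nearest"))
            names.append(f"laplacian_s{s}")
        if "hessian" in kinds:
            H = hessian_matrix(img, sigma=sigma, mode="nearest", use_gaussian_derivatives=False)
            for k, ev in enumerate(_sym3_eigvals(H)):
                feats.append(ev)
                names.append(f"hessian_ev{k}_s{s}")
        if "structure" in kinds:
            A = structure_tensor(img, sigma=sigma, mode="nearest")
            for k, ev in enumerate(_sym3_eigvals(A)):
                feats.append(ev)
                names.append(f"structure_ev{k}_s{s}")
    data = np.stack([f.astype(np.float32) for f in feats])
    return FeatureStack(data=data, names=names, scales=tuple(scales), spacing_um=channel.spacing_um)


@dataclass
class PixelClassifierModel:
    """A trained random-forest pixel classifier plus its feature recipe.

    Serializable with :meth:`save` / :meth:`load`; reloading reproduces
    identical predictions (the forest object is stored verbatim).
    """

    forest: RandomForestClassifier
    scales: tuple[float, ...]
    kinds: tuple[str, ...]
    spacing_um: tuple[float, float, float]
    rng_seed: int
    holdout_accuracy: float = float("nan")
    training_provenance: str = ""
    threshold: float = 0.5

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PixelClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a PixelClassifierModel")
        return model


def train_pixel_classifier(
    features: FeatureStack,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
    provenance: str = "",
) -> PixelClassifierModel:
    """Fit the random-forest pixel classifier from sparse voxel labels.

    ``labels`` is a volume with 0 = unlabeled, 1 = structure,
    2 = background; at least 50 labeled voxels per class are required.  A
    25% stratified hold-out reports accuracy, after which the forest is
    refit on all labels.  Fixed seed ⇒ identical model.
    """
    labels = np.asarray(labels)
    if labels.shape != features.data.shape[1:]:
        raise ValueError("label volume shape does not match the feature stack")
    mask = labels > 0
    y = labels[mask]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels must contain both structure and background voxels")
    counts = {int(c): int((y == c).sum()) for c in classes}
    if min(counts.values()) < 50:
        raise ValueError(f"need >= 50 labeled voxels per class, got {counts}")
    X = features.data[:, mask].T

    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.25, random_state=seed, stratify=y)
    probe = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    probe.fit(X_tr, y_tr)
    acc = float(probe.score(X_te, y_te))

    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return PixelClassifierModel(
        forest=forest,
        scales=features.scales,
        kinds=tuple(sorted({n.split("_s")[0].split("_ev")[0] for n in features.names})),
        spacing_um=features.spacing_um,
        rng_seed=seed,
        holdout_accuracy=acc,
        training_provenance=provenance,
    )


def predict_mask(
    model: PixelClassifierModel,
    channel: VoxelGrid,
    threshold: float | None = None,
    chunk_voxels: int = 2_000_000,
    features: FeatureStack | None = None,
) -> tuple[VoxelGrid, np.ndarray]:
    """Apply the classifier: returns the structure probability grid and the
    binary mask ``p >= threshold`` (default 0.5).

    Pass ``features`` to reuse an already computed stack (it must match the
    model's feature recipe); otherwise the stack is recomputed here.
    """
    if not np.allclose(model.spacing_um, channel.spacing_um, rtol=1e-6):
        raise ValueError(
            f"model was trained at spacing {model.spacing_um} but channel has {channel.spacing_um}"
        )
    threshold = model.threshold if threshold is None else threshold
    kinds = tuple(k for k in _FEATURE_KINDS if k in model.kinds)
    if features is not None:
        if features.scales != tuple(model.scales) or features.data.shape[1:] != channel.shape:
            raise ValueError("supplied feature stack does not match the model/channel")
        feats = features
    else:
        feats = extract_features(channel, scales=model.scales, kinds=kinds)
    X = feats.flat()
    struct_col = int(np.where(model.forest.classes_ == 1)[0][0])
    prob = np.empty(X.shape[0], dtype=np.float32)
    for start in range(0, X.shape[0], chunk_voxels):
        sl = slice(start, start + chunk_voxels)
        prob[sl] = model.forest.predict_proba(X[sl])[:, struct_col]
    prob3 = prob.reshape(channel.shape)
    return channel.with_data(prob3, channel.channel + "_prob"), prob3 >= threshold


def threshold_absolute(channel: VoxelGrid, tau: float) -> np.ndarray:
    """Absolute-intensity segmentation: ``intensity >= tau``."""
    return np.asarray(channel.data) >= tau


def subtract_background(channel: VoxelGrid, radius_um: float = 10.0) -> VoxelGrid:
    """Remove slowly varying background with a grayscale opening of the
    given physical radius.

    The opening is computed with a separable axis-aligned box (1D min then
    max filters) whose half-width along each axis is the radius converted to
    voxels — an O(N) approximation of a ball-shaped rolling element that
    preserves smooth backgrounds exactly in the monotone case.  Structures
    thinner than the radius are removed from the background estimate, so
    subtracting it preserves tubes while flattening the diffuse signal.
    Output is clipped at 0.
    """
    import warnings

    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    img = np.asarray(channel.data, dtype=np.float32)
    size = []
    for sp in channel.spacing_um:
        r_vox = int(round(radius_um / sp))
        if r_vox < 1:
            warnings.warn(
                f"background radius {radius_um} μm is below one voxel at spacing {sp} μm; clamping to 1 voxel",
                stacklevel=2,
            )
            r_vox = 1
        size.append(2 * r_vox + 1)
    eroded = ndimage.minimum_filter(img, size=size, mode="nearest")
    background = ndimage.maximum_filter(eroded, size=size, mode="nearest")
    return channel.with_data(np.clip(img - background, 0.0, None))


def label_components(mask: np.ndarray, spacing_um: tuple[float, float, float]) -> tuple[LabelVolume, pd.DataFrame]:
    """26-connectivity connected components with physical per-object stats.

    Returns the label volume and an object table with voxel counts, volumes
    in μm³ and centroids in μm.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    lv = LabelVolume(labels.astype(np.int32), spacing_um)
    if n == 0:
        return lv, empty_object_table()
    idx = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    centroids = np.asarray(ndimage.center_of_mass(mask, labels, idx), dtype=float)
    sp = np.asarray(spacing_um)
    table = pd.DataFrame(
        {
            "label": idx,
            "n_voxels": counts.astype(int),
            "volume_um3": counts * voxel_volume_um3(spacing_um),
            "centroid_z_um": centroids[:, 0] * sp[0],
            "centroid_y_um": centroids[:, 1] * sp[1],
            "centroid_x_um": centroids[:, 2] * sp[2],
        }
    )
    return lv, table


def filter_by_volume(table: pd.DataFrame, min_volume_um3: float = 1e4) -> pd.DataFrame:
    """Drop subcellular-sized objects: retain ``volume_um3 >= min_volume_um3``
    (inclusive threshold)."""
    if len(table) == 0:
        return table.copy()
    return table[table["volume_um3"] >= min_volume_um3].reset_index(drop=True)


def mask_from_table(labels: LabelVolume, table: pd.DataFrame) -> np.ndarray:
    """Binary mask of exactly the objects present in ``table``."""
    if len(table) == 0:
        return np.zeros(labels.shape, dtype=bool)
    keep = np.zeros(labels.n_objects + 1, dtype=bool)
    keep[table["label"].to_numpy()] = True
    return keep[labels.labels]


def sample_training_labels(
    truth_mask: np.ndarray,
    n_structure: int,
    rng: np.random.Generator,
    n_background: int | None = None,
    near_fraction: float = 0.5,
    near_reach_vox: int = 5,
) -> np.ndarray:
    """Build a sparse training-label volume from a reference mask.

    Structure voxels (label 1) are sampled from the mask.  Background
    voxels (label 2, ``3 * n_structure`` by default) are drawn half from a
    band within ``near_reach_vox`` voxels of the structures and half from
    the far field — the way an annotator paints background tightly around
    the structures being traced, which is what teaches the classifier a
    sharp boundary.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    n_background = 3 * n_structure if n_background is None else n_background
    labels = np.zeros(truth_mask.shape, dtype=np.uint8)
    fg = np.flatnonzero(truth_mask.ravel())
    near = ndimage.binary_dilation(truth_mask, iterations=near_reach_vox) & ~truth_mask
    bg_near = np.flatnonzero(near.ravel())
    bg_far = np.flatnonzero((~truth_mask & ~near).ravel())
    n_near = min(int(round(near_fraction * n_background)), len(bg_near))
    n_far = n_background - n_near
    if len(fg) < n_structure or len(bg_far) < n_far:
        raise ValueError("not enough voxels to sample the requested labels")
    flat = labels.ravel()
    flat[rng.choice(fg, size=n_structure, replace=False)] = 1
    if n_near:
        flat[rng.choice(bg_near, size=n_near, replace=False)] = 2
    flat[rng.choice(bg_far, size=n_far, replace=False)] = 2
    return flat.reshape(truth_mask.shape)
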