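"""End-to-end orchestration: channels in, quantitative results out.

Stage order mirrors the imaging study's processing chain: (optional VOI
crop) → initial segmentation at full resolution (classifier for the nerve
channel, background subtraction + absolute threshold for the vessel
channels) → 10⁴ μm³ volume filter → volume densities → down-sample masks
×2 → split into ~10 μm objects → vessel phenotype classification →
periosteal/dural assignment from the fitted mid-surface → per-object
shortest distances and association fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, regionalization, segmentation, spatial_quant, vessel_phenotyping
from .config import PipelineConfig
from .grids import LabelVolume, VoxelGrid, voxel_volume_um3
from .phantom import PHENOTYPES, GroundTruth, PhantomSpec, generate_phantom

__all__ = ["QuantResult", "run_pipeline"]

log = logging.getLogger("qlsm.pipeline")


@dataclass
class QuantResult:
    """Per-run quantitative output, ready for group statistics."""

    densities: dict = field(default_factory=dict)  # structure -> volume / region volume
    phenotype_fractions: dict = field(default_factory=dict)
    compartment: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    nerve_objects: pd.DataFrame | None = None
    vessel_objects: pd.DataFrame | None = None
    distances: pd.DataFrame | None = None
    config_hash: str = ""
    ground_truth: GroundTruth | None = None

    def long_table(self, sample: str = "sample", group: str = "", region: str = "") -> pd.DataFrame:
        """Flatten to the long format consumed by :mod:`qlsm.stats_report`."""
        rows = []

        def add(metric, name, value):
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "region": region,
                    "compartment": name if metric == "compartment_fraction" else "",
                    "metric": f"{metric}_{name}" if metric != "compartment_fraction" else metric,
                    "value": value,
                }
            )

        for k, v in self.densities.items():
            add("volume_density", k, v)
        for k in PHENOTYPES:
            if k in self.phenotype_fractions:
                add("phenotype_fraction", k, self.phenotype_fractions[k])
        for k in ("periosteal_fraction", "dural_fraction"):
            if k in self.compartment:
                add("compartment_fraction", k.split("_")[0], self.compartment[k])
        for k, v in self.association.items():
            add("association_fraction", k, v)
        return pd.DataFrame(rows)


def _load_channels(config: PipelineConfig) -> tuple[dict[str, VoxelGrid], GroundTruth | None]:
    if config.phantom is not None:
        spec = PhantomSpec(**{**config.phantom, "rng_seed": config.phantom.get("rng_seed", config.seed)})
        log.info("generating phantom, shape=%s seed=%d", spec.volume_shape_vox, spec.rng_seed)
        return generate_phantom(spec)
    channels = {
        name: io.read_volume(path, fallback_spacing_um=config.fallback_spacing_um, channel=name)
        for name, path in config.input_paths.items()
    }
    return channels, None


def _nerve_mask(config: PipelineConfig, channel: VoxelGrid, gt: GroundTruth | None) -> np.ndarray:
    """Initial nerve segmentation: trained pixel classifier, or a plain
    absolute threshold when ``thresholds.nerve_tau`` is set."""
    if config.thresholds.nerve_tau is not None:
        return segmentation.threshold_absolute(channel, config.thresholds.nerve_tau)
    cc = config.classifier
    rng = np.random.default_rng(config.seed + 101)
    if cc.labels_csv is not None:
        rows = pd.read_csv(cc.labels_csv)
        labels = np.zeros(channel.shape, dtype=np.uint8)
        labels[rows["z"].to_numpy(), rows["y"].to_numpy(), rows["x"].to_numpy()] = rows["class"].to_numpy()
        provenance = f"labels_csv:{cc.labels_csv}"
    elif gt is not None:
        labels = segmentation.sample_training_labels(gt.nerve_label, cc.n_labels_per_class, rng)
        provenance = "ground-truth sampled labels"
    else:
        raise ValueError("nerve classifier needs labels_csv (real data) or a phantom ground truth")
    feats = segmentation.extract_features(channel, scales=cc.scales)
    model = segmentation.train_pixel_classifier(
        feats, labels, seed=config.seed, n_estimators=cc.n_estimators, provenance=provenance
    )
    log.info("nerve classifier hold-out accuracy: %.3f", model.holdout_accuracy)
    _, mask = segmentation.predict_mask(model, channel, threshold=cc.probability_threshold, features=feats)
    return mask


def _vessel_mask(config: PipelineConfig, channel: VoxelGrid, tau: float) -> np.ndarray:
    cleaned = segmentation.subtract_background(channel, radius_um=config.background_radius_um)
    return segmentation.threshold_absolute(cleaned, tau)


def _filtered_mask(config, mask, spacing) -> tuple[np.ndarray, pd.DataFrame]:
    lv, table = segmentation.label_components(mask, spacing)
    kept = segmentation.filter_by_volume(table, config.min_volume_um3)
    return segmentation.mask_from_table(lv, kept), kept


def run_pipeline(
    config: PipelineConfig,
    channels: dict[str, VoxelGrid] | None = None,
    ground_truth: GroundTruth | None = None,
) -> QuantResult:
    """Execute all stages for one sample / VOI.

    ``channels`` and ``ground_truth`` may be passed to reuse an already
    generated phantom; otherwise they come from the config (phantom spec or
    TIFF paths).  Deterministic given the config (fixed seeds throughout).
    """
    if channels is None:
        channels, ground_truth = _load_channels(config)
    for name in ("nerve", "cd31", "emcn"):
        if name not in channels:
            raise ValueError(f"missing channel {name!r}")
    spacing = channels["nerve"].spacing_um
    region_volume = float(np.prod(channels["nerve"].shape)) * voxel_volume_um3(spacing)

    if config.vois:
        vois = [regionalization.VOISpec(**v) for v in config.vois]
        if len(vois) != 1:
            raise NotImplementedError("run_pipeline processes one VOI per call; loop externally")
        channels = {k: regionalization.crop_voi(g, vois[0]) for k, g in channels.items()}
        region_volume = float(np.prod(channels["nerve"].shape)) * voxel_volume_um3(spacing)

    result = QuantResult(config_hash=config.config_hash(), ground_truth=ground_truth)

    # --- initial segmentation, full resolution ---------------------------
    log.info("segmenting nerve channel")
    nerve_mask_raw = _nerve_mask(config, channels["nerve"], ground_truth)
    nerve_mask, nerve_table = _filtered_mask(config, nerve_mask_raw, spacing)
    log.info("segmenting vessel channels")
    cd31_mask, _ = _filtered_mask(config, _vessel_mask(config, channels["cd31"], config.thresholds.cd31_tau), spacing)
    emcn_mask, _ = _filtered_mask(config, _vessel_mask(config, channels["emcn"], config.thresholds.emcn_tau), spacing)

    voxvol = voxel_volume_um3(spacing)
    result.densities = {
        "nerve": spatial_quant.volume_density(float(nerve_mask.sum()) * voxvol, region_volume),
        "cd31": spatial_quant.volume_density(float(cd31_mask.sum()) * voxvol, region_volume),
        "emcn": spatial_quant.volume_density(float(emcn_mask.sum()) * voxvol, region_volume),
        "vessel_union": spatial_quant.volume_density(float((cd31_mask | emcn_mask).sum()) * voxvol, region_volume),
    }

    # --- down-sampled object analysis ------------------------------------
    f = config.downsample_factor
    ds_spacing = tuple(s * f for s in spacing)
    nerve_ds = vessel_phenotyping.downsample_mask(nerve_mask, f)
    cd31_ds = vessel_phenotyping.downsample_mask(cd31_mask, f)
    emcn_ds = vessel_phenotyping.downsample_mask(emcn_mask, f)

    log.info("splitting objects (seed diameter %.1f μm)", config.seed_diameter_um)
    nerve_split = vessel_phenotyping.split_objects(nerve_ds, ds_spacing, config.seed_diameter_um)
    cd31_split = vessel_phenotyping.split_objects(cd31_ds, ds_spacing, config.seed_diameter_um)
    emcn_split = vessel_phenotyping.split_objects(emcn_ds, ds_spacing, config.seed_diameter_um)

    rules = vessel_phenotyping.PhenotypeRuleSet(
        cd31_hi_threshold=config.thresholds.cd31_tau,
        emcn_hi_threshold=config.thresholds.emcn_tau,
        overlap_min_voxels=config.overlap_min_voxels,
    )
    vessel_table, phen_map = vessel_phenotyping.classify_phenotype(cd31_split, emcn_split, rules)
    result.vessel_objects = vessel_table
    result.phenotype_fractions = vessel_phenotyping.phenotype_fractions(phen_map, ds_spacing)

    # --- compartments -----------------------------------------------------
    log.info("fitting mid-surface and assigning compartments")
    from scipy import ndimage as ndi

    # tubes are sparse in any single (y, x) column: pool laterally (~20 μm)
    # so each column sees the extremes of both vascular bands around it
    union = cd31_ds | emcn_ds
    ry = max(1, int(round(20.0 / ds_spacing[1])))
    rx = max(1, int(round(20.0 / ds_spacing[2])))
    yy, xx = np.ogrid[-ry : ry + 1, -rx : rx + 1]
    disk = ((yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0)[None, :, :]
    pooled = ndi.binary_dilation(union, structure=disk)
    vessel_ref = VoxelGrid(pooled, ds_spacing, channel="vessel_union")
    surface = regionalization.fit_mid_surface(vessel_ref)
    nerve_obj_table = _split_table(nerve_split)
    nerve_obj_table = regionalization.classify_compartment(nerve_obj_table, surface)
    result.nerve_objects = nerve_obj_table
    half_volumes = _side_volumes(surface, nerve_split)
    result.compartment = regionalization.compartment_fractions(nerve_obj_table, half_volumes)

    # --- spatial association ----------------------------------------------
    log.info("computing shortest distances")
    phen_masks = {p: phen_map == k for k, p in enumerate(PHENOTYPES, start=1)}
    distances = spatial_quant.shortest_distances(nerve_split, phen_masks)
    result.distances = distances.merge(nerve_obj_table[["label", "compartment"]], on="label", how="left")
    result.association = spatial_quant.association_fraction(distances, config.association_d_um)

    if config.out_dir:
        _write_outputs(config, result, channels, spacing)
    return result


def _split_table(split: LabelVolume) -> pd.DataFrame:
    from scipy import ndimage

    n = split.n_objects
    if n == 0:
        from .grids import empty_object_table

        return empty_object_table()
    idx = np.arange(1, n + 1)
    counts = np.bincount(split.labels.ravel(), minlength=n + 1)[1:]
    cent = np.asarray(ndimage.center_of_mass(split.mask(), split.labels, idx), dtype=float)
    sp = np.asarray(split.spacing_um)
    return pd.DataFrame(
        {
            "label": idx,
            "n_voxels": counts.astype(int),
            "volume_um3": counts * split.voxel_volume_um3,
            "centroid_z_um": cent[:, 0] * sp[0],
            "centroid_y_um": cent[:, 1] * sp[1],
            "centroid_x_um": cent[:, 2] * sp[2],
        }
    )


def _side_volumes(surface: "regionalization.MidSurface", grid: LabelVolume) -> dict:
    """Volumes of the outer and inner halves of the stack split by the
    mid-surface (the normalizers for compartment volume densities)."""
    nz = grid.shape[0]
    dz = grid.spacing_um[0]
    z = np.arange(nz) * dz + grid.origin_um[0]
    above = (z[:, None, None] <= surface.height_um[None, :, :]).sum()
    total = np.prod(grid.shape)
    voxvol = grid.voxel_volume_um3
    return {"periosteal": float(above) * voxvol, "dural": float(total - above) * voxvol}


def _write_outputs(config: PipelineConfig, result: QuantResult, channels, spacing) -> None:
    from pathlib import Path

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if result.nerve_objects is not None:
        result.nerve_objects.to_csv(out / "nerve_objects.csv", index=False, float_format="%.10g")
    if result.vessel_objects is not None:
        result.vessel_objects.to_csv(out / "vessel_objects.csv", index=False, float_format="%.10g")
    if result.distances is not None:
        result.distances.to_csv(out / "nerve_distances.csv", index=False, float_format="%.10g")
    summary = pd.DataFrame(
        [
            {"metric": f"volume_density_{k}", "value": v}
            for k, v in result.densities.items()
        ]
        + [{"metric": f"phenotype_fraction_{k}", "value": result.phenotype_fractions.get(k)} for k in PHENOTYPES]
        + [
            {"metric": f"compartment_{k}", "value": v}
            for k, v in result.compartment.items()
        ]
        + [{"metric": f"association_fraction_{k}", "value": v} for k, v in result.association.items()]
    )
    summary.to_csv(out / "quant_summary.csv", index=False, float_format="%.10g")
    if config.write_intermediates:
        for name, grid in channels.items():
            io.write_volume(grid, out / f"channel_{name}.ome.tif")
    logging.getLogger("qlsm").info("outputs written to %s (config %s)", out, result.config_hash)
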