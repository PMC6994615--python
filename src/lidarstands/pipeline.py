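"""End-to-end orchestration: simulate, rasterize, classify, composite,
segment, features, fit, inventory, evaluate — with a JSON manifest
recording seeds, hashes and per-stage timing."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lidarstands import features as feat
from lidarstands import inventory as inv
from lidarstands import io as lio
from lidarstands import raster as ras
from lidarstands import rvm as rvm_mod
from lidarstands import segmentation as seg
from lidarstands import synthetic as syn
from lidarstands.params import load_parameter_group
from lidarstands.raster import LAND_COVER_CLASSES


@dataclass
class PipelineConfig:
    seed: int = 0
    scene: syn.SceneConfig | None = None
    n_plots: int = 94
    n_train: int = 60
    parameter_group: int = 5
    percentile: float = 85.0
    vegetation_height_threshold: float = 1.0
    cell_size: float = 20.0
    median_window: int = 3
    mean_shift_spatial_radius: float = 2.0
    mean_shift_spectral: tuple[float, float] = (0.1, 2.0)  # density, height
    training_pixels_per_class: int = 200
    rvm: rvm_mod.RVMConfig = field(default_factory=rvm_mod.RVMConfig)
    run_loo: bool = False


@dataclass
class PipelineResult:
    config: PipelineConfig
    scene: syn.GroundTruth
    dem: ras.RasterGrid
    height: ras.RasterGrid
    density: ras.RasterGrid
    classified: ras.RasterGrid
    kappa: float
    composite: ras.CompositeDHH
    label_grid: ras.RasterGrid
    polygons: dict
    comparison: dict
    feature_table: feat.FeatureTable
    models: dict[str, rvm_mod.RVMModel]
    train_ids: list
    validation_ids: list
    stand_table: pd.DataFrame
    metrics: pd.DataFrame
    loo: dict[str, rvm_mod.LOOResult] | None
    manifest: dict


def _estimate_class_stats(
    bands: list[ras.RasterGrid],
    truth_codes: ras.RasterGrid,
    n_per_class: int,
    rng: np.random.Generator,
) -> tuple[dict, tuple[str, ...], np.ndarray]:
    """Per-class per-band mean/sd from a random training sample, plus the
    truth codes of a held-out-style full comparison."""
    codes = truth_codes.values.astype(int)
    stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order: list[str] = []
    for code in np.unique(codes):
        name = LAND_COVER_CLASSES[code]
        rows, cols = np.nonzero(codes == code)
        pick = rng.choice(rows.size, size=min(n_per_class, rows.size), replace=False)
        sample = np.stack([b.values[rows[pick], cols[pick]] for b in bands])
        sds = sample.std(axis=1)
        stats[name] = (sample.mean(axis=1), np.where(sds > 0, sds, 1e-6))
        order.append(name)
    return stats, tuple(order), codes


def run_pipeline(config: PipelineConfig | None = None, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline; optionally persist artifacts + manifest."""
    config = config or PipelineConfig()
    streams = np.random.SeedSequence(config.seed).spawn(8)
    sub_seed = lambda i: int(np.random.default_rng(streams[i]).integers(2**31))
    timing: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        timing[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    # 1. simulate
    scene_cfg = config.scene or syn.SceneConfig(rng_seed=config.seed)
    scene = syn.generate_scene(scene_cfg, n_plots=config.n_plots)
    extent = scene_cfg.extent
    tick("simulate")

    # 2. rasterize: DEM from classified ground returns, then the bands
    dem = ras.grid_min_dem(scene.cloud.ground(), scene_cfg.pixel_size_m, extent)
    normalized = ras.normalize_heights(scene.cloud, dem)
    height = ras.height_percentile_raster(normalized, extent, scene_cfg.pixel_size_m, config.percentile)
    density = ras.density_raster(
        normalized, extent, scene_cfg.pixel_size_m, config.vegetation_height_threshold
    )
    tick("rasterize")

    # 3. classify the aerial image (training pixels sampled from truth)
    stats, order, truth_codes = _estimate_class_stats(
        scene.image_bands, scene.class_grid, config.training_pixels_per_class,
        np.random.default_rng(sub_seed(1)),
    )
    classified_local = ras.ml_classify(scene.image_bands, stats, order)
    # map local class indices back to global land-cover codes
    lut = np.array([LAND_COVER_CLASSES.index(name) for name in order])
    classified = ras.RasterGrid(
        lut[classified_local.values.astype(int)].astype(float),
        classified_local.origin, classified_local.pixel_size, semantic="class_label",
    )
    n_classes = len(LAND_COVER_CLASSES)
    confusion = np.zeros((n_classes, n_classes))
    np.add.at(confusion, (truth_codes.ravel(), classified.values.astype(int).ravel()), 1)
    present = confusion.sum(axis=1) + confusion.sum(axis=0) > 0
    kappa = (
        1.0
        if present.sum() < 2
        else ras.kappa_coefficient(confusion[np.ix_(present, present)])
    )
    tick("classify")

    # 4. filter + composite
    sr = config.mean_shift_spatial_radius
    dens_f = ras.mean_shift_filter(
        ras.median_filter(density, config.median_window), sr, config.mean_shift_spectral[0]
    )
    hght_f = ras.mean_shift_filter(
        ras.median_filter(height, config.median_window), sr, config.mean_shift_spectral[1]
    )
    composite = ras.build_composite(dens_f, hght_f, classified)
    tick("composite")

    # 5. segment
    seg_params, merge_params = load_parameter_group(config.parameter_group)
    label_grid, polygons, _ = seg.segment_stands(composite, seg_params, merge_params)
    comparison = seg.compare_segmentations(
        label_grid.values.astype(int), scene.stand_grid.values.astype(int)
    )
    tick("segment")

    # 6. plot features
    table = feat.feature_matrix(scene.plots, normalized)
    measured = inv.measured_table(scene.plots)
    tick("features")

    # 7. fit on a random train split, one model per parameter
    rng = np.random.default_rng(sub_seed(2))
    ids = list(table.X.index)
    perm = rng.permutation(len(ids))
    train_ids = [ids[i] for i in perm[: config.n_train]]
    valid_ids = [ids[i] for i in perm[config.n_train :]]
    models: dict[str, rvm_mod.RVMModel] = {}
    loo: dict[str, rvm_mod.LOOResult] | None = {} if config.run_loo else None
    for name in inv.PARAMETER_ORDER:
        y = measured.loc[train_ids, name].to_numpy(dtype=float)
        models[name] = rvm_mod.rvm_fit(table.X.loc[train_ids], y, config.rvm)
        if config.run_loo:
            loo[name] = rvm_mod.loo_validate(table.X.loc[train_ids], y, config.rvm)  # type: ignore[index]
    tick("fit")

    # 8. stand inventory
    cells = inv.tessellate_cells(label_grid, config.cell_size)
    cells = inv.predict_cells(cells, normalized, models)
    stand_table = inv.aggregate_to_stands(cells)
    tick("inventory")

    # 9. evaluate at the validation plots
    valid_plots = [p for p in scene.plots if p.plot_id in set(valid_ids)]
    predicted = inv.predict_plots(valid_plots, normalized, models)
    metrics = inv.evaluate_inventory(predicted, measured.loc[predicted.index, list(inv.PARAMETER_ORDER)])
    tick("evaluate")

    manifest: dict = {
        "seed": config.seed,
        "parameter_group": config.parameter_group,
        "timing_s": timing,
        "stages": list(timing),
        "kappa": kappa,
        "segment_count": comparison["count_a"],
        "true_stand_count": comparison["count_b"],
        "adjusted_rand_index": comparison["adjusted_rand_index"],
    }

    result = PipelineResult(
        config=config, scene=scene, dem=dem, height=height, density=density,
        classified=classified, kappa=kappa, composite=composite,
        label_grid=label_grid, polygons=polygons, comparison=comparison,
        feature_table=table, models=models, train_ids=train_ids,
        validation_ids=valid_ids, stand_table=stand_table, metrics=metrics,
        loo=loo, manifest=manifest,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    from lidarstands import points as pts

    pts.write_csv(result.scene.cloud, out / "points.csv")
    ras.write_ascii_grid(result.dem, out / "dem.asc")
    ras.write_ascii_grid(result.height, out / "height.asc")
    ras.write_ascii_grid(result.density, out / "density.asc")
    ras.write_ascii_grid(result.classified, out / "classes.asc")
    ras.write_ascii_grid(result.label_grid, out / "stands.asc")
    ras.write_ascii_grid(result.scene.stand_grid, out / "stands_truth.asc")
    lio.write_geojson(result.polygons, out / "stands.geojson")
    lio.write_tree_csv(result.scene.plots, out / "plot_trees.csv")
    lio.write_plot_csv(result.scene.plots, out / "plots.csv")
    result.feature_table.X.to_csv(out / "features.csv")
    inv.measured_table(result.scene.plots).to_csv(out / "plot_params.csv")
    (out / "models").mkdir(exist_ok=True)
    for name, model in result.models.items():
        model.to_json(out / "models" / f"{name}.json")
    result.stand_table.to_csv(out / "stand_inventory.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    manifest = dict(result.manifest)
    manifest["artifacts"] = {
        p.name: _sha256(p) for p in sorted(out.rglob("*")) if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
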