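"""End-to-end pipeline: simulate/ingest -> normalize -> align -> rasterize
-> label -> train -> evaluate.

Each stage writes its artifacts under the configured output directory and
the run finishes with a JSON report (counts, metrics, file paths).  Every
artifact is re-derivable from the config and seed alone.

The height axis after principal-axes alignment is centred on the plot
centroid, so rasterization adds back the centroid's height component
(axes[2] @ centroid); raster values are then height above ground again, and
the lodged-patch average recovers h1*cos(theta).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import classify as cl
from .hotelling import HotellingResult, hotelling_transform
from .lodging import FIELD_THRESHOLDS, classify_LI
from .normalize import ExGConfig, build_dem, normalize_cloud, split_ground
from .pointcloud import PlotLayout, PointCloud, crop_plots, read_xyz_txt
from .raster import IDWConfig, Raster, idw, make_grid, render_image
from .synthetic import FieldSimConfig, generate_field

logger = logging.getLogger("lodgepoint")

__all__ = ["process_plot", "raster_patch_mean", "run_pipeline"]


def process_plot(
    cloud: PointCloud,
    exg_threshold: float = 0.0729,
    dem_spacing: float = 0.1,
    raster_spacing: float = 0.01,
    k_neighbors: int = 12,
) -> tuple[Raster, HotellingResult]:
    """Normalize, align and rasterize one plot cloud.

    Returns the canopy-height raster (heights above ground, metres) and the
    principal-axes transform used for alignment.
    """
    from .normalize import exg_scores

    exg = exg_scores(cloud)
    ground_mask = exg < exg_threshold
    if ground_mask.sum() < 3:
        raise ValueError("not enough ground points to normalize the plot")
    dem = build_dem(cloud.select(ground_mask), spacing=dem_spacing)
    normalized = normalize_cloud(cloud, dem)
    # The raster plane is the plot's ground plane: estimate the principal
    # axes from the normalized ground points (canopy height structure would
    # tilt the height axis) and apply that rigid transform to the canopy.
    hot = hotelling_transform(normalized.select(ground_mask))
    veg = normalized.select(~ground_mask)
    if veg.n == 0:
        raise ValueError("no vegetation points to rasterize")
    # rasterize the canopy only: interpolating bare-soil points into the
    # surface would bias canopy heights low wherever soil shows through
    t = veg.with_coords((veg.coords - hot.centroid) @ hot.axes.T)
    dx = float(t.x.max() - t.x.min())
    dy = float(t.y.max() - t.y.min())
    grid = make_grid(dx, dy, raster_spacing, origin=(float(t.x.min()), float(t.y.min())))
    raster = idw(t, grid, IDWConfig(k_neighbors=k_neighbors))
    # restore the translation dropped along the height axis
    raster.values += float(hot.axes[2] @ hot.centroid)
    return raster, hot


def raster_patch_mean(
    raster: Raster, hot: HotellingResult, bounds: tuple[float, float, float, float]
) -> float:
    """Mean raster height over cells whose centres fall in a world-xy box."""
    gx, gy = raster.grid.cell_centers()
    pts = np.column_stack([gx, gy, np.zeros_like(gx)])
    world = pts @ hot.axes + hot.centroid  # inverse of V (P - m), z' ~ 0
    x_lo, x_hi, y_lo, y_hi = bounds
    inside = (world[:, 0] >= x_lo) & (world[:, 0] < x_hi) & \
             (world[:, 1] >= y_lo) & (world[:, 1] < y_hi)
    if not inside.any():
        raise ValueError("patch does not intersect the raster")
    return float(raster.values.ravel()[inside].mean())


def _stage_simulate(cfg: dict, seed: int):
    sim_kwargs = {k: v for k, v in cfg.items() if k not in ("n_plots", "class_mix", "seed")}
    sim = FieldSimConfig(seed=seed, **sim_kwargs)
    n_plots = int(cfg.get("n_plots", 8))
    field, truths, manifest, layout = generate_field(
        sim, n_plots, cfg.get("class_mix", "balanced"), seed=seed
    )
    plots = crop_plots(field, layout)
    labels = {t.plot_id: int(t.lodging_class) for t in truths}
    return plots, labels, manifest


def _stage_ingest(cfg: dict):
    cloud_path = Path(cfg["cloud"])
    if not cloud_path.is_file():
        raise FileNotFoundError(f"input cloud not found: {cloud_path}")
    cloud = read_xyz_txt(cloud_path)
    lay = cfg.get("layout", {})
    layout = PlotLayout(
        origin=tuple(lay.get("origin", (0.0, 0.0))),
        plot_length=float(lay.get("plot_length", 7.8)),
        plot_width=float(lay.get("plot_width", 3.8)),
        n_rows=int(lay.get("n_rows", 1)),
        n_cols=int(lay.get("n_cols", 1)),
    )
    plots = crop_plots(cloud, layout)
    labels = {}
    meas = cfg.get("measurements")
    if meas:
        from .lodging import read_measurements_csv

        for m in read_measurements_csv(meas):
            labels[m.plot_id] = int(m.lodging_class if m.lodging_class is not None
                                    else classify_LI(m.LI, FIELD_THRESHOLDS))
    return plots, labels, None


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write artifacts plus report.json."""
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "lodgepoint_run"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "out_dir": str(out), "stages": []}
    t0 = time.time()

    if "simulate" in config:
        plots, labels, manifest = _stage_simulate(config.get("simulate", {}), seed)
        if manifest is not None:
            manifest.to_csv(out / "truth.csv", index=False)
            report["truth_csv"] = str(out / "truth.csv")
    elif "ingest" in config:
        plots, labels, _ = _stage_ingest(config["ingest"])
    else:
        raise ValueError("config needs a 'simulate' or 'ingest' stage")
    report["stages"].append("input")
    report["n_plots"] = len(plots)

    rcfg = config.get("rasterize", {})
    ncfg = config.get("normalize", {})
    png_dir = out / "rasters"
    png_dir.mkdir(exist_ok=True)
    samples: list[cl.ImageSample] = []
    png_paths: list[str] = []
    for pid, cloud in plots:
        raster, hot = process_plot(
            cloud,
            exg_threshold=float(ncfg.get("exg_threshold", 0.0729)),
            dem_spacing=float(ncfg.get("dem_spacing", 0.1)),
            raster_spacing=float(rcfg.get("spacing", 0.05)),
            k_neighbors=int(rcfg.get("k_neighbors", 12)),
        )
        img = render_image(raster, float(rcfg.get("z_min", 0.0)),
                           float(rcfg.get("z_max", 1.2)),
                           rcfg.get("colormap", "viridis"))
        path = png_dir / f"plot_{pid:03d}.png"
        Image.fromarray(img).save(path)
        png_paths.append(str(path))
        if pid in labels:
            samples.append(cl.ImageSample(image=img, label=labels[pid], source_plot=pid))
    report["stages"] += ["normalize", "align", "rasterize"]
    report["rendered_pngs"] = png_paths

    ccfg = config.get("classify", {})
    if ccfg.get("enabled", True) and samples:
        target = int(ccfg.get("target_total", max(len(samples), 25)))
        augmented = cl.augment_dataset(samples, target, seed=seed)
        splitter = cl.split_by_plot if ccfg.get("split_by_plot") else cl.split_dataset
        train, val, test = splitter(augmented, seed=seed)
        tc = cl.TrainConfig(
            model_name=ccfg.get("model", "mobilenetv2"),
            learning_rate=float(ccfg.get("learning_rate", 0.001)),
            batch_size=int(ccfg.get("batch_size", 4)),
            max_epochs=int(ccfg.get("max_epochs", 400)),
            patience=int(ccfg.get("patience", 30)),
            seed=seed,
            input_size=int(ccfg.get("input_size", 224)),
            width_mult=float(ccfg.get("width_mult", 1.0)),
        )
        model, history = cl.train_model(train, val, tc)
        ev = cl.evaluate_model(model, test, input_size=tc.input_size)
        report["stages"] += ["train", "evaluate"]
        report["dataset"] = {"total": len(augmented), "train": len(train),
                             "val": len(val), "test": len(test)}
        report["training"] = {"epochs_run": history["epochs_run"],
                              "best_epoch": history["best_epoch"],
                              "best_val_accuracy": max(history["val_accuracy"])}
        report["metrics"] = {
            "accuracy": ev.accuracy,
            "macro_precision": ev.macro_precision,
            "macro_recall": ev.macro_recall,
            "macro_f1": ev.macro_f1,
            "confusion": ev.confusion.tolist(),
        }
    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
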