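"""Synthetic wheat-field point clouds with known lodging ground truth.

Emulates the field survey the pipeline is built for: rectangular plots
(default 7.8 m x 3.8 m) on gently undulating terrain, a green canopy at
height h1 with a contiguous lodged patch of area fraction LR whose canopy
sits at h2 = h1*cos(theta), brown soil visible between plants, and Gaussian
height noise.  Because theta and LR are injected, every downstream stage
has an exact oracle: ExG separation should recover the soil points, DEM
normalization should recover height above ground, and raster heights inside
the patch should average h1*cos(theta).

The colour model keeps soil and canopy chromatically well separated
(soil ExG stays below ~0.04, canopy above ~0.5 at default jitter), so the
default ExG threshold of 0.0729 splits them exactly.

What it does not emulate: per-plant canopy structure, occlusion and
reconstruction artefacts of photogrammetry, wind-blown intermediate angles
within a patch, or mixed soil/canopy pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lodging import FIELD_THRESHOLDS, LodgingClass, classify_LI, lodging_index
from .pointcloud import PlotLayout, PointCloud

__all__ = [
    "FieldSimConfig",
    "PlotTruth",
    "CLASS_THETA_RANGES",
    "generate_plot",
    "generate_field",
]

#: Lodging-angle sampling ranges (degrees) per degree class.  The implied
#: canopy heights h1*cos(theta) at h1 = 1 m fall into the four observed
#: height bands: > 0.9 m, 0.7-0.9 m, 0.5-0.7 m, < 0.5 m.
CLASS_THETA_RANGES: dict[LodgingClass, tuple[float, float]] = {
    LodgingClass.non_lodging: (0.0, 10.0),
    LodgingClass.slight: (25.0, 40.0),
    LodgingClass.moderate: (45.0, 60.0),
    LodgingClass.severe: (70.0, 90.0),
}


@dataclass(frozen=True)
class FieldSimConfig:
    """Simulation parameters; defaults mirror the surveyed field protocol."""

    plot_length: float = 7.8       # m, along x
    plot_width: float = 3.8        # m, along y
    point_density: float = 500.0   # points / m^2
    h1: float = 1.0                # upright canopy height, m
    terrain_base: float = 50.0     # m, absolute elevation offset
    terrain_slope: tuple[float, float] = (0.01, 0.02)  # dz/dx, dz/dy
    terrain_amp: float = 0.08      # m, sinusoid amplitude
    terrain_wavelength: float = 6.0  # m
    noise_sigma: float = 0.02      # m, Gaussian height noise
    soil_fraction: float = 0.2     # fraction of points hitting bare soil
    canopy_rgb: tuple[int, int, int] = (60, 140, 60)
    soil_rgb: tuple[int, int, int] = (150, 100, 60)
    color_jitter: int = 5          # per-channel uniform jitter, +-
    seed: int = 0

    def __post_init__(self) -> None:
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.soil_fraction < 1:
            raise ValueError("soil_fraction must lie in [0, 1)")

    def terrain(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Ground elevation at world (x, y)."""
        ax, ay = self.terrain_slope
        w = 2 * math.pi / self.terrain_wavelength
        return (
            self.terrain_base + ax * x + ay * y
            + self.terrain_amp * np.sin(w * x) * np.sin(w * y)
        )


@dataclass
class PlotTruth:
    """Ground truth for one generated plot."""

    plot_id: int
    h1: float
    theta: float            # degrees
    h2: float               # realized lodged canopy height, h1*cos(theta)
    LR: float
    LA: float
    LI: float
    lodging_class: LodgingClass
    patch_bounds: tuple[float, float, float, float] | None  # x_lo, x_hi, y_lo, y_hi
    soil_mask: np.ndarray | None = None
    lodged_mask: np.ndarray | None = None


def _patch_rectangle(cfg: FieldSimConfig, LR: float, origin: tuple[float, float],
                     rng: np.random.Generator) -> tuple[float, float, float, float] | None:
    """Axis-aligned rectangle inside the plot with area fraction exactly LR."""
    if LR <= 0:
        return None
    area = LR * cfg.plot_length * cfg.plot_width
    aspect = rng.uniform(0.5, 2.0)
    wp = math.sqrt(area * aspect)
    lp = area / wp
    if wp > cfg.plot_width:
        wp = cfg.plot_width
        lp = area / wp
    if lp > cfg.plot_length:
        lp = cfg.plot_length
        wp = area / lp
    x0 = origin[0] + rng.uniform(0, cfg.plot_length - lp)
    y0 = origin[1] + rng.uniform(0, cfg.plot_width - wp)
    return (x0, x0 + lp, y0, y0 + wp)


def _jitter_colors(base: tuple[int, int, int], n: int, jitter: int,
                   rng: np.random.Generator) -> np.ndarray:
    rgb = np.tile(np.asarray(base, dtype=float), (n, 1))
    rgb *= rng.uniform(0.8, 1.2, size=(n, 1))  # brightness, chromaticity-neutral
    rgb += rng.integers(-jitter, jitter + 1, size=(n, 3))
    return np.clip(np.rint(rgb), 0, 255).astype(int)


def generate_plot(
    cfg: FieldSimConfig,
    theta: float,
    LR: float,
    plot_id: int = 1,
    origin: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> tuple[PointCloud, PlotTruth]:
    """Generate one plot's colored cloud plus its truth record.

    ``theta`` (degrees) and ``LR`` are the injected lodging angle and
    lodged-area fraction; the truth LI and class follow from the severity
    formulas under the field thresholds.
    """
    if not 0 <= theta <= 90:
        raise ValueError("theta must lie in [0, 90] degrees")
    if not 0 <= LR <= 1:
        raise ValueError("LR must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = max(10, int(round(cfg.point_density * cfg.plot_length * cfg.plot_width)))
    x = origin[0] + rng.uniform(0, cfg.plot_length, n)
    y = origin[1] + rng.uniform(0, cfg.plot_width, n)
    soil = rng.random(n) < cfg.soil_fraction
    patch = _patch_rectangle(cfg, LR, origin, rng)
    if patch is None:
        in_patch = np.zeros(n, dtype=bool)
    else:
        x_lo, x_hi, y_lo, y_hi = patch
        in_patch = (x >= x_lo) & (x < x_hi) & (y >= y_lo) & (y < y_hi)
    lodged = in_patch & ~soil
    h2 = cfg.h1 * math.cos(math.radians(theta))
    height = np.where(soil, 0.0, np.where(lodged, h2, cfg.h1))
    z = cfg.terrain(x, y) + height + rng.normal(0.0, cfg.noise_sigma, n)
    colors = np.empty((n, 3), dtype=int)
    colors[soil] = _jitter_colors(cfg.soil_rgb, int(soil.sum()), cfg.color_jitter, rng)
    colors[~soil] = _jitter_colors(cfg.canopy_rgb, int((~soil).sum()), cfg.color_jitter, rng)
    cloud = PointCloud(np.column_stack([x, y, z]), colors)
    LA = theta / 90.0
    LI = lodging_index(LA, LR)
    truth = PlotTruth(
        plot_id=plot_id, h1=cfg.h1, theta=theta, h2=h2, LR=LR, LA=LA, LI=LI,
        lodging_class=classify_LI(LI), patch_bounds=patch,
        soil_mask=soil, lodged_mask=lodged,
    )
    return cloud, truth


def _spec_for_class(cls: LodgingClass, rng: np.random.Generator) -> tuple[float, float]:
    """Sample (theta, LR) whose LI lands inside the class's LI interval."""
    lo, mid, hi = FIELD_THRESHOLDS.boundaries
    intervals = {
        LodgingClass.non_lodging: (0.0, lo),
        LodgingClass.slight: (lo, mid),
        LodgingClass.moderate: (mid, hi),
        LodgingClass.severe: (hi, 1.0),
    }
    theta = rng.uniform(*CLASS_THETA_RANGES[cls])
    LA = theta / 90.0
    if cls is LodgingClass.non_lodging:
        # any LR keeps LI = LA*LR below the first cut because LA < mu-alpha
        return theta, float(rng.uniform(0.0, 1.0))
    li_lo, li_hi = intervals[cls]
    li_hi = min(li_hi, LA)
    if li_hi <= li_lo:
        raise ValueError(f"infeasible class spec for {cls!r} at theta={theta:.1f}")
    li = rng.uniform(li_lo, li_hi)
    return theta, float(li / LA)


def _resolve_mix(class_mix, n_plots: int) -> list[LodgingClass]:
    if class_mix == "balanced":
        classes = [LodgingClass(i % 4) for i in range(n_plots)]
    elif isinstance(class_mix, dict):
        classes = []
        for cls, count in class_mix.items():
            classes += [LodgingClass(cls)] * int(count)
        if len(classes) != n_plots:
            raise ValueError("class_mix counts do not sum to n_plots")
    else:
        classes = [LodgingClass(c) for c in class_mix]
        if len(classes) != n_plots:
            raise ValueError("class_mix list length != n_plots")
    return classes


def generate_field(
    cfg: FieldSimConfig,
    n_plots: int,
    class_mix="balanced",
    seed: int | None = None,
    keep_masks: bool = True,
) -> tuple[PointCloud, list[PlotTruth], pd.DataFrame, PlotLayout]:
    """Generate a tiled field of plots hitting a requested class mix.

    Returns the merged field cloud, per-plot truths, a manifest DataFrame
    (plot_id, theta, LR, LA, LI, class) and the plot layout.  Deterministic
    for a given seed.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    classes = _resolve_mix(class_mix, n_plots)
    n_cols = int(math.ceil(math.sqrt(n_plots)))
    n_rows = int(math.ceil(n_plots / n_cols))
    layout = PlotLayout(
        origin=(0.0, 0.0), plot_length=cfg.plot_length, plot_width=cfg.plot_width,
        n_rows=n_rows, n_cols=n_cols,
    )
    clouds, truths, rows = [], [], []
    for pid, cls in enumerate(classes, start=1):
        theta, LR = _spec_for_class(cls, rng)
        x_lo, _, y_lo, _ = layout.plot_bounds(pid)
        cloud, truth = generate_plot(cfg, theta, LR, plot_id=pid,
                                     origin=(x_lo, y_lo), rng=rng)
        if truth.lodging_class != cls:
            raise AssertionError("generated LI fell outside the requested class")
        if not keep_masks:
            truth.soil_mask = None
            truth.lodged_mask = None
        clouds.append(cloud)
        truths.append(truth)
        rows.append({
            "plot_id": pid, "theta": theta, "LR": LR, "LA": truth.LA,
            "LI": truth.LI, "class": cls.name,
        })
    coords = np.vstack([c.coords for c in clouds])
    colors = np.vstack([c.colors for c in clouds])
    return PointCloud(coords, colors), truths, pd.DataFrame(rows), layout
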