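"""Ground/vegetation separation and terrain normalization.

Photogrammetric point clouds carry absolute elevations, so canopy height is
confounded with terrain undulation.  The pipeline removes the terrain in
three steps:

1. The Excess Green index ExG = 2g - r - b on chromatic coordinates
   (r = R/(R+G+B), ...) separates brown soil (low ExG) from green canopy
   (high ExG); the default cut-off is 0.0729.
2. A digital elevation model (DEM) is interpolated from the ground points
   onto a coarse grid (default 0.1 m spacing) with IDW.
3. Every point's z is replaced by z - DEM(x, y), sampling the DEM
   bilinearly, leaving height above ground.

Negative normalized heights are kept rather than clamped: they expose
interpolation bias and the rasterizer can clip for rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pointcloud import PointCloud
from .raster import GridSpec, IDWConfig, idw, make_grid

logger = logging.getLogger("lodgepoint")

__all__ = [
    "ExGConfig",
    "DEM",
    "exg_scores",
    "split_ground",
    "build_dem",
    "normalize_cloud",
]


@dataclass(frozen=True)
class ExGConfig:
    """Excess-Green threshold separating ground (below) from canopy."""

    threshold: float = 0.0729


@dataclass
class DEM:
    """Terrain elevation on a coarse grid (metres)."""

    grid: GridSpec
    elevation: np.ndarray

    def __post_init__(self) -> None:
        if self.elevation.shape != (self.grid.rows, self.grid.cols):
            raise ValueError("elevation shape does not match grid")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("DEM has non-finite cells")

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear terrain elevation at (x, y); raises if outside extent."""
        g = self.grid
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = g.origin
        outside = (
            (x < x0) | (x > x0 + g.rows * g.d) | (y < y0) | (y > y0 + g.cols * g.d)
        )
        if np.any(outside):
            i = int(np.argmax(outside))
            raise ValueError(
                f"point ({x.flat[i]:.3f}, {y.flat[i]:.3f}) lies outside the DEM extent"
            )
        # continuous cell-centre coordinates, clamped to the centre lattice
        fi = np.clip((x - x0) / g.d - 0.5, 0.0, g.rows - 1.0)
        fj = np.clip((y - y0) / g.d - 0.5, 0.0, g.cols - 1.0)
        i0 = np.clip(np.floor(fi).astype(int), 0, max(g.rows - 2, 0))
        j0 = np.clip(np.floor(fj).astype(int), 0, max(g.cols - 2, 0))
        i1 = np.minimum(i0 + 1, g.rows - 1)
        j1 = np.minimum(j0 + 1, g.cols - 1)
        ti = fi - i0
        tj = fj - j0
        e = self.elevation
        return (
            e[i0, j0] * (1 - ti) * (1 - tj)
            + e[i1, j0] * ti * (1 - tj)
            + e[i0, j1] * (1 - ti) * tj
            + e[i1, j1] * ti * tj
        )


def exg_scores(cloud: PointCloud) -> np.ndarray:
    """Per-point Excess Green index on chromatic coordinates.

    ExG = 2g - r - b with r = R/(R+G+B) etc.; black points (R+G+B = 0)
    score 0.  Pure green scores 2, neutral gray 0.
    """
    if cloud.colors is None:
        raise ValueError("ExG needs per-point RGB colors")
    rgb = cloud.colors.astype(float)
    s = rgb.sum(axis=1)
    safe = np.where(s == 0, 1.0, s)
    r, g, b = (rgb[:, i] / safe for i in range(3))
    exg = 2 * g - r - b
    exg[s == 0] = 0.0
    return exg


def split_ground(
    cloud: PointCloud, cfg: ExGConfig = ExGConfig()
) -> tuple[PointCloud, PointCloud]:
    """Partition a colored cloud into (ground, vegetation) by ExG threshold."""
    exg = exg_scores(cloud)
    ground_mask = exg < cfg.threshold
    if not ground_mask.any():
        logger.warning("split_ground: no ground points below ExG threshold; DEM cannot be built")
    ground = cloud.select(ground_mask)
    vegetation = cloud.select(~ground_mask)
    return ground, vegetation


def build_dem(
    ground: PointCloud,
    grid: GridSpec | None = None,
    spacing: float = 0.1,
    idw_cfg: IDWConfig = IDWConfig(),
) -> DEM:
    """IDW-interpolate ground elevations onto a coarse grid.

    When no grid is given, one is built over the ground cloud's xy bounding
    box at ``spacing``.  Every cell gets a value (IDW over the k nearest
    ground samples never leaves a cell empty while ground is non-empty).
    """
    if ground.n == 0:
        raise ValueError("cannot build a DEM from an empty ground cloud")
    if grid is None:
        # one-cell margin so vegetation slightly beyond the ground bbox
        # still falls inside the DEM extent
        dx = max(float(ground.x.max() - ground.x.min()), spacing) + 2 * spacing
        dy = max(float(ground.y.max() - ground.y.min()), spacing) + 2 * spacing
        origin = (float(ground.x.min()) - spacing, float(ground.y.min()) - spacing)
        grid = make_grid(dx, dy, spacing, origin=origin)
    raster = idw(ground, grid, idw_cfg)
    return DEM(grid=grid, elevation=raster.values)


def normalize_cloud(cloud: PointCloud, dem: DEM) -> PointCloud:
    """Subtract the DEM from point elevations, yielding height above ground."""
    dz = dem.sample(cloud.x, cloud.y)
    coords = cloud.coords.copy()
    coords[:, 2] -= dz
    return cloud.with_coords(coords)
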