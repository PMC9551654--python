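"""Point-cloud containers and I/O.

UAV photogrammetry exports field point clouds as plain-text XYZ (one point
per line, optionally with RGB).  This module reads and writes that format,
optionally ingests PLY, and cuts a whole-field cloud into per-plot clouds on
a rectangular plot layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("lodgepoint")

__all__ = [
    "PointCloud",
    "PlotLayout",
    "read_xyz_txt",
    "write_xyz_txt",
    "read_ply",
    "crop_plots",
]


@dataclass
class PointCloud:
    """A set of n 3D points, optionally with per-point 8-bit RGB.

    ``coords`` is an (n, 3) float array in metres; ``colors`` is an
    (n, 3) integer array in [0, 255] or None.
    """

    coords: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != self.coords.shape:
                raise ValueError(
                    f"colors shape {self.colors.shape} != coords shape {self.coords.shape}"
                )
            if self.colors.min(initial=0) < 0 or self.colors.max(initial=0) > 255:
                raise ValueError("color channels must lie in [0, 255]")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]

    def select(self, mask_or_index) -> "PointCloud":
        """Subset the cloud by boolean mask or integer index array."""
        colors = None if self.colors is None else self.colors[mask_or_index]
        return PointCloud(self.coords[mask_or_index], colors)

    def with_coords(self, coords: np.ndarray) -> "PointCloud":
        """Same colors, new coordinates (e.g. after a rigid transform)."""
        return PointCloud(np.asarray(coords, dtype=float), self.colors)


@dataclass
class PlotLayout:
    """Rectangular grid of field plots.

    The layout origin is the lower-left corner of plot 1; plots are numbered
    row-major starting at 1 (rows advance along y, columns along x).
    """

    origin: tuple[float, float] = (0.0, 0.0)
    plot_length: float = 7.8
    plot_width: float = 3.8
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.plot_length <= 0 or self.plot_width <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout needs at least one row and one column")

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.n_cols

    def plot_bounds(self, plot_id: int) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, y_lo, y_hi) of a 1-based row-major plot id."""
        if not 1 <= plot_id <= self.n_plots:
            raise ValueError(f"plot_id {plot_id} outside 1..{self.n_plots}")
        r, c = divmod(plot_id - 1, self.n_cols)
        x0, y0 = self.origin
        x_lo = x0 + c * self.plot_length
        y_lo = y0 + r * self.plot_width
        return x_lo, x_lo + self.plot_length, y_lo, y_lo + self.plot_width


def _parse_line(line: str) -> list[float]:
    return [float(t) for t in line.replace(",", " ").split()]


def read_xyz_txt(path: str | Path, has_colors: bool | None = None) -> PointCloud:
    """Read a plain-text XYZ(+RGB) cloud.

    Accepts whitespace- or comma-separated columns; lines starting with
    ``#`` and blank lines are ignored.  3 columns give coordinates only,
    6 columns give coordinates plus RGB.  ``has_colors`` forces the
    interpretation; by default it is inferred from the first data line.

    Raises FileNotFoundError for a missing file and ValueError (naming the
    line number) for a malformed line.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"point cloud file not found: {path}")
    coords: list[list[float]] = []
    colors: list[list[float]] = []
    expect: int | None = None if has_colors is None else (6 if has_colors else 3)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals = _parse_line(line)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse line {line!r}") from exc
            if expect is None:
                if len(vals) not in (3, 6):
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 or 6 columns, got {len(vals)}"
                    )
                expect = len(vals)
            if len(vals) != expect:
                raise ValueError(
                    f"{path}:{lineno}: expected {expect} columns, got {len(vals)}"
                )
            coords.append(vals[:3])
            if expect == 6:
                colors.append(vals[3:])
    if not coords:
        raise ValueError(f"{path}: no data lines")
    col_arr = np.rint(np.asarray(colors)).astype(int) if colors else None
    return PointCloud(np.asarray(coords, dtype=float), col_arr)


def write_xyz_txt(cloud: PointCloud, path: str | Path) -> Path:
    """Write a cloud as XYZ text, 6 columns when colors are present."""
    if cloud.n == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    if cloud.colors is None:
        data = cloud.coords
        fmt = ["%.6f"] * 3
    else:
        data = np.column_stack([cloud.coords, cloud.colors])
        fmt = ["%.6f"] * 3 + ["%d"] * 3
    np.savetxt(path, data, fmt=fmt)
    return path


def read_ply(path: str | Path) -> PointCloud:
    """Read a PLY point cloud (convenience path; XYZ text is normative)."""
    import trimesh

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"point cloud file not found: {path}")
    obj = trimesh.load(str(path), process=False)
    coords = np.asarray(obj.vertices, dtype=float)
    colors = None
    vc = getattr(obj, "colors", None)
    if vc is None and hasattr(obj, "visual"):
        vc = getattr(obj.visual, "vertex_colors", None)
    if vc is not None:
        vc = np.asarray(vc)
        if vc.ndim == 2 and vc.shape[0] == coords.shape[0] and vc.shape[1] >= 3:
            colors = vc[:, :3].astype(int)
    return PointCloud(coords, colors)


def crop_plots(cloud: PointCloud, layout: PlotLayout) -> list[tuple[int, PointCloud]]:
    """Cut a field cloud into per-plot clouds.

    Plot rectangles are half-open, [x_lo, x_hi) x [y_lo, y_hi), so a point
    on a shared boundary belongs to exactly one plot.  Points outside every
    plot are dropped.  Returns (plot_id, cloud) pairs for non-empty plots,
    ordered by plot id; an empty intersection yields an empty list and a
    warning.
    """
    out: list[tuple[int, PointCloud]] = []
    x, y = cloud.x, cloud.y
    for pid in range(1, layout.n_plots + 1):
        x_lo, x_hi, y_lo, y_hi = layout.plot_bounds(pid)
        mask = (x >= x_lo) & (x < x_hi) & (y >= y_lo) & (y < y_hi)
        if mask.any():
            out.append((pid, cloud.select(mask)))
    if not out:
        logger.warning("crop_plots: layout does not intersect the cloud; no plots cut")
    return out
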