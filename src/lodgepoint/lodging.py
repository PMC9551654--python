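"""Lodging severity: angle, area, index, and the double-threshold degree.

A lodged stem makes an angle theta with the vertical (0 deg upright, 90 deg
flat).  In the field one measures the sloping plant height h1 and the canopy
height h2, so sin(90 - theta) = h2/h1 and

    theta = 90 - arcsin(h2 / h1)          [degrees]
    LA    = 2*theta/pi = theta/90         [0..1, angle severity]
    LI    = LA * LR                       [0..1, lodging index]

with LR the lodged-area fraction of the plot.  Plots are then binned into
four degrees (non/slight/moderate/severe) by the double-threshold strategy:
the mean mu and standard deviation alpha of LI over all surveyed plots give
cut points mu - alpha, mu, mu + alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LodgingClass",
    "LodgingThresholds",
    "PlotMeasurement",
    "lodging_angle",
    "lodging_LA",
    "lodging_index",
    "thresholds_from_LI",
    "classify_LI",
    "measure_plot",
    "read_measurements_csv",
    "write_measurements_csv",
]

#: Field-survey thresholds over 360 plots: mean 0.40, SD 0.274.
FIELD_MU = 0.40
FIELD_ALPHA = 0.274


class LodgingClass(IntEnum):
    """Four lodging degrees, ordered by severity."""

    non_lodging = 0
    slight = 1
    moderate = 2
    severe = 3


@dataclass(frozen=True)
class LodgingThresholds:
    """Double-threshold cut points derived from the LI distribution."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        lo, hi = self.mu - self.alpha, self.mu + self.alpha
        if not (0 <= lo < self.mu < hi <= 1):
            raise ValueError(
                f"degenerate thresholds: need 0 <= mu-alpha < mu < mu+alpha <= 1, "
                f"got mu={self.mu}, alpha={self.alpha}"
            )

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (self.mu - self.alpha, self.mu, self.mu + self.alpha)


#: Thresholds realized by the reference field survey (mu=0.40, alpha=0.274),
#: giving intervals [0, 0.126), [0.126, 0.40), [0.40, 0.674), [0.674, 1].
FIELD_THRESHOLDS = LodgingThresholds(FIELD_MU, FIELD_ALPHA)


@dataclass
class PlotMeasurement:
    """Per-plot lodging measurement and derived severity quantities."""

    plot_id: int
    h1: float
    h2: float
    theta: float
    LA: float
    LR: float
    LI: float
    lodging_class: LodgingClass | None = None


def _check_heights(h1: float, h2: float) -> None:
    if h1 <= 0:
        raise ValueError(f"plant height h1 must be positive, got {h1}")
    if not 0 <= h2 <= h1:
        raise ValueError(f"canopy height must satisfy 0 <= h2 <= h1, got h2={h2}, h1={h1}")


def lodging_angle(h1: float, h2: float) -> float:
    """Lodging angle in degrees from sloping height h1 and canopy height h2."""
    _check_heights(h1, h2)
    return 90.0 - math.degrees(math.asin(h2 / h1))


def lodging_LA(h1: float, h2: float) -> float:
    """Angle severity LA = 2*theta/pi in [0, 1]."""
    return lodging_angle(h1, h2) / 90.0


def lodging_index(LA: float, LR: float) -> float:
    """Lodging index LI = LA * LR; 0 is upright growth, 1 complete lodging."""
    if not 0 <= LA <= 1:
        raise ValueError(f"LA must lie in [0, 1], got {LA}")
    if not 0 <= LR <= 1:
        raise ValueError(f"LR must lie in [0, 1], got {LR}")
    return LA * LR


def thresholds_from_LI(li_values: Sequence[float]) -> LodgingThresholds:
    """Mean/population-SD thresholds from the LI values of surveyed plots."""
    li = np.asarray(li_values, dtype=float)
    if li.size < 2:
        raise ValueError("need at least 2 plots to derive thresholds")
    mu = float(li.mean())
    alpha = float(li.std())  # population SD (ddof=0)
    return LodgingThresholds(mu, alpha)


def classify_LI(li: float, t: LodgingThresholds = FIELD_THRESHOLDS) -> LodgingClass:
    """Assign the four-class lodging degree to a lodging index.

    Intervals are half-open on the right except the last:
    [0, mu-a) -> non_lodging, [mu-a, mu) -> slight, [mu, mu+a) -> moderate,
    [mu+a, 1] -> severe.  A boundary value belongs to the upper class.
    """
    if not 0 <= li <= 1:
        raise ValueError(f"LI must lie in [0, 1], got {li}")
    lo, mid, hi = t.boundaries
    if li < lo:
        return LodgingClass.non_lodging
    if li < mid:
        return LodgingClass.slight
    if li < hi:
        return LodgingClass.moderate
    return LodgingClass.severe


def measure_plot(
    plot_id: int,
    height_pairs: Iterable[tuple[float, float]],
    LR: float,
    thresholds: LodgingThresholds | None = FIELD_THRESHOLDS,
) -> PlotMeasurement:
    """Summarise one plot from field samples.

    ``height_pairs`` are 3-5 (h1, h2) tape measurements; their lodging
    angles are averaged before LA, matching the field protocol.
    """
    pairs = list(height_pairs)
    if not pairs:
        raise ValueError("need at least one (h1, h2) pair")
    thetas = [lodging_angle(h1, h2) for h1, h2 in pairs]
    theta = float(np.mean(thetas))
    LA = theta / 90.0
    LI = lodging_index(LA, LR)
    h1_mean = float(np.mean([p[0] for p in pairs]))
    h2_mean = float(np.mean([p[1] for p in pairs]))
    cls = classify_LI(LI, thresholds) if thresholds is not None else None
    return PlotMeasurement(plot_id, h1_mean, h2_mean, theta, LA, LR, LI, cls)


def write_measurements_csv(measurements: Sequence[PlotMeasurement], path: str | Path) -> Path:
    rows = [
        {
            "plot_id": m.plot_id,
            "h1": m.h1,
            "h2": m.h2,
            "theta": m.theta,
            "LA": m.LA,
            "LR": m.LR,
            "LI": m.LI,
            "class": m.lodging_class.name if m.lodging_class is not None else "",
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_measurements_csv(path: str | Path) -> list[PlotMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        cls = LodgingClass[r["class"]] if isinstance(r.get("class"), str) and r["class"] else None
        out.append(
            PlotMeasurement(
                int(r["plot_id"]), float(r["h1"]), float(r["h2"]), float(r["theta"]),
                float(r["LA"]), float(r["LR"]), float(r["LI"]), cls,
            )
        )
    return out
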