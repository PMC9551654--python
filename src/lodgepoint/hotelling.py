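"""Principal-axes (Hotelling) alignment of a plot's point cloud.

The cloud is translated to its centroid m and rotated by the eigenvector
matrix V of its population covariance C so that the transformed axes carry
descending variance and the covariance becomes diagonal:

    m  = (1/n) sum P_k
    C  = (1/n) sum (P_k - m)(P_k - m)^T
    P' = V (P_k - m)

For a field plot the two large-variance axes span the ground plane and the
smallest-variance axis is the canopy-height direction, so the downstream
raster grid is axis-aligned with the plot regardless of how the UAV survey
was oriented.

Eigenvector signs are fixed deterministically: the height axis (axis 3)
points toward world up, axis 1 toward world +x (falling back to +y when
orthogonal), and axis 2 = axis3 x axis1, which forces det(V) = +1 (a proper
rotation, never a mirror image).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pointcloud import PointCloud

logger = logging.getLogger("lodgepoint")

__all__ = ["HotellingResult", "centroid", "covariance", "hotelling_transform"]

_DEGENERACY_RTOL = 1e-12


@dataclass
class HotellingResult:
    """Centroid, principal axes and the transformed cloud.

    ``axes`` rows are unit eigenvectors ordered by descending eigenvalue;
    ``transformed.coords[k] = axes @ (coords[k] - centroid)``.
    """

    centroid: np.ndarray
    covariance: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray
    transformed: PointCloud


def centroid(cloud: PointCloud) -> np.ndarray:
    """Centre of gravity of the cloud (arithmetic mean of coordinates)."""
    if cloud.n == 0:
        raise ValueError("centroid of an empty cloud is undefined")
    return cloud.coords.mean(axis=0)


def covariance(cloud: PointCloud) -> np.ndarray:
    """Population (divide-by-n) covariance of the coordinates.

    Computed in the centered form (1/n) sum (P_k - m)(P_k - m)^T, which is
    algebraically identical to the uncentered (1/n) sum P_k P_k^T - m m^T
    but numerically stable for clouds far from the origin.
    """
    if cloud.n == 0:
        raise ValueError("covariance of an empty cloud is undefined")
    d = cloud.coords - cloud.coords.mean(axis=0)
    return d.T @ d / cloud.n


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention; rows are axes 1..3 (descending var)."""
    a1, a3 = vecs[0].copy(), vecs[2].copy()
    if a3 @ np.array([0.0, 0.0, 1.0]) < 0:
        a3 = -a3
    d = a1 @ np.array([1.0, 0.0, 0.0])
    if abs(d) > 1e-9:
        if d < 0:
            a1 = -a1
    elif a1 @ np.array([0.0, 1.0, 0.0]) < 0:
        a1 = -a1
    a2 = np.cross(a3, a1)
    return np.vstack([a1, a2, a3])


def hotelling_transform(cloud: PointCloud) -> HotellingResult:
    """Rotate/translate a cloud into its principal-axes frame."""
    if cloud.n < 3:
        raise ValueError("need at least 3 points for a principal-axes transform")
    m = centroid(cloud)
    C = covariance(cloud)
    evals, evecs = np.linalg.eigh(C)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T  # rows = eigenvectors, descending eigenvalue
    if evals[0] <= _DEGENERACY_RTOL:
        raise ValueError("degenerate cloud: all points (numerically) identical")
    if evals[2] <= _DEGENERACY_RTOL * evals[0]:
        logger.info("rank-deficient cloud (coplanar or collinear points)")
    gaps = np.abs(np.diff(evals))
    if np.any(gaps < _DEGENERACY_RTOL * evals[0]):
        logger.info("near-equal eigenvalues; axis order stabilized by sign convention")
    V = _fix_signs(evecs)
    transformed = cloud.with_coords((cloud.coords - m) @ V.T)
    return HotellingResult(m, C, V, np.clip(evals, 0.0, None), transformed)
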