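"""3D shape descriptors and first-order intensity-histogram features.

Shape features are computed on the binary tumor mask: *solidity* (fraction of
the convex hull that the lesion fills), *extent* (fraction of the tight
axis-aligned bounding box that the lesion fills) and *eccentricity*
(elongation of the best-fit ellipsoid of the voxel cloud).  All three are
voxel-counting definitions, so they are invariant to axis permutations and
flips of the volume.

Histogram features are population moments of the in-mask intensities:
minimum, median, mean, variance (divisor ``n``), skewness ``m3 / m2**1.5``
and Pearson (non-excess) kurtosis ``m4 / m2**2`` — a normal distribution has
kurtosis 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import DegenerateMaskError, EmptyMaskError

__all__ = [
    "ShapeFeatures",
    "HistogramFeatures",
    "solidity",
    "extent",
    "eccentricity",
    "shape_features",
    "histogram_features",
]


@dataclass(frozen=True)
class ShapeFeatures:
    solidity: float
    extent: float
    eccentricity: float


@dataclass(frozen=True)
class HistogramFeatures:
    minimum: float
    median: float
    mean: float
    variance: float
    skewness: float
    kurtosis: float


def _foreground_points(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {mask.shape}")
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    return pts


def solidity(mask: np.ndarray) -> float:
    """Lesion volume divided by its convex-hull volume, both in voxels.

    The hull volume is counted as the number of grid voxels whose centers lie
    inside or on the convex hull of the foreground voxel centers, so a convex
    digital body has solidity exactly 1.  Requires at least 4 non-coplanar
    foreground voxels; degenerate (flat) masks raise
    :class:`~bcsradiomics.errors.DegenerateMaskError`.
    """
    pts = _foreground_points(mask)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateMaskError(
            "convex hull undefined: foreground voxels are coplanar or collinear"
        ) from exc
    tri = Delaunay(pts[hull.vertices])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij")
    candidates = np.stack([g.ravel() for g in grids], axis=1)
    inside = tri.find_simplex(candidates) >= 0
    n_hull = int(inside.sum())
    return min(1.0, pts.shape[0] / n_hull)


def extent(mask: np.ndarray) -> float:
    """Lesion volume divided by the volume of its tight axis-aligned bounding box."""
    pts = _foreground_points(mask)
    box = np.prod(pts.max(axis=0) - pts.min(axis=0) + 1)
    return float(pts.shape[0] / box)


def eccentricity(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Meridional eccentricity of the ellipsoid fit to the voxel cloud.

    Computed as ``sqrt(1 - lambda_min / lambda_max)`` from the extreme
    eigenvalues of the covariance of foreground voxel centers scaled by the
    voxel spacing (mm), so anisotropic voxels contribute their physical
    elongation.  A ball gives ~0; a single voxel is defined as 0.
    """
    pts = _foreground_points(mask).astype(float) * np.asarray(spacing, dtype=float)
    if pts.shape[0] == 1:
        return 0.0
    cov = np.cov(pts, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)
    lam_max = eigvals[-1]
    if lam_max <= 0.0:
        return 0.0
    ratio = max(0.0, eigvals[0] / lam_max)
    return float(np.sqrt(1.0 - ratio))


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> ShapeFeatures:
    """All three shape descriptors of a mask in one pass."""
    return ShapeFeatures(
        solidity=solidity(mask),
        extent=extent(mask),
        eccentricity=eccentricity(mask, spacing),
    )


def histogram_features(values: np.ndarray, mask: np.ndarray | None = None) -> HistogramFeatures:
    """First-order statistics of the in-mask intensity histogram.

    ``values`` is either a 3D intensity volume (with ``mask`` selecting the
    ROI) or a flat vector of in-mask intensities.  Variance uses divisor
    ``n``; the median of an even count is the midpoint of the two central
    order statistics.  If the ROI is constant (zero variance), skewness and
    kurtosis are undefined and reported as NaN rather than 0.
    """
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    v = v.ravel()
    if v.size == 0:
        raise EmptyMaskError("no in-mask intensities")
    mean = float(v.mean())
    centered = v - mean
    m2 = float(np.mean(centered**2))
    if m2 > 0.0:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2)
    else:
        skew = float("nan")
        kurt = float("nan")
    return HistogramFeatures(
        minimum=float(v.min()),
        median=float(np.median(v)),
        mean=mean,
        variance=m2,
        skewness=skew,
        kurtosis=kurt,
    )
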