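"""Gray-level texture matrices for 3D regions of interest.

In-mask intensities are first quantized to ``L`` equal-width levels (default
16, mirroring the coarse quantization typical of clinical DCE-MRI texture
analysis).  Two matrices are then built:

* **GLCM** (gray-level co-occurrence matrix): joint probability of level
  pairs at a fixed voxel offset, accumulated symmetrically over the 13
  unique 3D directions and normalized.  Summarized by energy, entropy
  (bits), homogeneity (inverse difference) and contrast.
* **GLSZM** (gray-level size zone matrix): counts of maximal connected
  zones of equal level, indexed by level and zone size, summarized by the
  standard 11 zone-emphasis / nonuniformity / percentage statistics.

Conventions that the literature leaves open are pinned here and exposed as
arguments: GLCM offset distance 1, one aggregated matrix over all
directions, homogeneity with a ``1 + |i - j|`` denominator, GLSZM zone
connectivity 26 (switchable to 6), per-scan equal-width quantization over
the in-mask range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BcsRadiomicsError, EmptyMaskError

__all__ = [
    "QuantizedRoi",
    "Glcm",
    "Glszm",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "compute_glszm",
    "glszm_features",
    "GLCM_FEATURE_NAMES",
    "GLSZM_FEATURE_NAMES",
]

GLCM_FEATURE_NAMES = ("energy", "entropy", "homogeneity", "contrast")

GLSZM_FEATURE_NAMES = (
    "SZE",    # small-zone emphasis
    "LZE",    # large-zone emphasis
    "LIZE",   # low-intensity zone emphasis
    "HIZE",   # high-intensity zone emphasis
    "LISZE",  # low-intensity small-zone emphasis
    "HISZE",  # high-intensity small-zone emphasis
    "LILZE",  # low-intensity large-zone emphasis
    "HILZE",  # high-intensity large-zone emphasis
    "GLN",    # gray-level nonuniformity
    "ZSN",    # zone-size nonuniformity
    "ZP",     # zone percentage
)

# the 13 unique 3D directions: one representative per +/- offset pair
_OFFSETS_13 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)


@dataclass(frozen=True)
class QuantizedRoi:
    """In-mask intensities mapped to integer levels 1..L (0 outside the mask)."""

    levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


@dataclass(frozen=True)
class Glcm:
    """Symmetric, normalized L x L co-occurrence probability matrix."""

    p: np.ndarray
    offsets_used: tuple = field(default=_OFFSETS_13)


@dataclass(frozen=True)
class Glszm:
    """Zone counts: ``counts[i-1, j-1]`` = zones of level i with size j."""

    counts: np.ndarray
    n_zones: int
    n_voxels: int


def quantize(values: np.ndarray, mask: np.ndarray, n_levels: int = 16) -> QuantizedRoi:
    """Equal-width quantization of in-mask intensities into 1..n_levels.

    ``level = min(L, floor((v - min) / (max - min) * L) + 1)``; the in-mask
    minimum maps to level 1 and the maximum to level L.  A constant ROI is
    legal and maps every voxel to level 1.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    if not mask.any():
        raise EmptyMaskError("cannot quantize an empty ROI")
    v = values[mask]
    vmin, vmax = float(v.min()), float(v.max())
    levels = np.zeros(values.shape, dtype=np.int32)
    if vmax > vmin:
        lv = np.floor((v - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
        np.minimum(lv, n_levels, out=lv)
    else:
        lv = np.ones(v.shape, dtype=np.int32)
    levels[mask] = lv
    edges = np.linspace(vmin, vmax, n_levels + 1)
    return QuantizedRoi(levels=levels, n_levels=int(n_levels), bin_edges=edges)


def compute_glcm(q: QuantizedRoi, distance: int = 1, offsets=None) -> Glcm:
    """Aggregate co-occurrence matrix over 3D directions at a voxel distance.

    Each in-mask voxel pair separated by ``distance * offset`` contributes to
    both (i, j) and (j, i), yielding a symmetric matrix normalized to sum 1.
    Raises if the ROI contains no valid neighbor pair.
    """
    if offsets is None:
        offsets = _OFFSETS_13
    L = q.n_levels
    lv = q.levels
    counts = np.zeros((L, L), dtype=np.int64)
    for off in offsets:
        src_sl, dst_sl = [], []
        for dim, o in zip(lv.shape, (distance * c for c in off)):
            if abs(o) >= dim:
                break
            if o >= 0:
                src_sl.append(slice(0, dim - o))
                dst_sl.append(slice(o, dim))
            else:
                src_sl.append(slice(-o, dim))
                dst_sl.append(slice(0, dim + o))
        else:
            src = lv[tuple(src_sl)]
            dst = lv[tuple(dst_sl)]
            valid = (src > 0) & (dst > 0)
            if valid.any():
                i = src[valid] - 1
                j = dst[valid] - 1
                np.add.at(counts, (i, j), 1)
                np.add.at(counts, (j, i), 1)
    total = counts.sum()
    if total == 0:
        raise BcsRadiomicsError("GLCM undefined: no in-mask voxel pairs at this distance")
    return Glcm(p=counts / total, offsets_used=tuple(offsets))


def glcm_features(g: Glcm) -> dict[str, float]:
    """Energy, entropy (bits), homogeneity and contrast of a GLCM."""
    p = g.p
    L = p.shape[0]
    i, j = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
    nz = p > 0
    return {
        "energy": float(np.sum(p**2)),
        "entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "contrast": float(np.sum(p * (i - j) ** 2)),
    }


def compute_glszm(q: QuantizedRoi, connectivity: int = 26) -> Glszm:
    """Size-zone matrix: maximal connected components of equal level.

    ``connectivity`` is 26 (vertices/edges/faces) or 6 (faces only).
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    lv = q.levels
    n_voxels = int((lv > 0).sum())
    if n_voxels == 0:
        raise EmptyMaskError("cannot build a GLSZM over an empty ROI")
    zones: list[tuple[int, int]] = []  # (level, size)
    max_size = 1
    for level in range(1, q.n_levels + 1):
        binary = lv == level
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
            max_size = max(max_size, int(s))
    counts = np.zeros((q.n_levels, max_size), dtype=np.int64)
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return Glszm(counts=counts, n_zones=len(zones), n_voxels=n_voxels)


def glszm_features(z: Glszm) -> dict[str, float]:
    """The 11 standard GLSZM statistics.

    With ``P[i, j]`` the zone counts, ``N_z`` total zones and ``N_p`` in-mask
    voxels: emphasis statistics weight P by powers of the gray level i and
    zone size j (e.g. LZE = (1/N_z) sum P * j**2), GLN/ZSN square the
    marginal sums, and ZP = N_z / N_p.
    """
    if z.n_zones == 0:
        raise BcsRadiomicsError("GLSZM features undefined: no zones")
    P = z.counts.astype(float)
    L, S = P.shape
    i = np.arange(1, L + 1)[:, None].astype(float)
    j = np.arange(1, S + 1)[None, :].astype(float)
    nz = float(z.n_zones)
    return {
        "SZE": float(np.sum(P / j**2) / nz),
        "LZE": float(np.sum(P * j**2) / nz),
        "LIZE": float(np.sum(P / i**2) / nz),
        "HIZE": float(np.sum(P * i**2) / nz),
        "LISZE": float(np.sum(P / (i**2 * j**2)) / nz),
        "HISZE": float(np.sum(P * i**2 / j**2) / nz),
        "LILZE": float(np.sum(P * j**2 / i**2) / nz),
        "HILZE": float(np.sum(P * i**2 * j**2) / nz),
        "GLN": float(np.sum(P.sum(axis=1) ** 2) / nz),
        "ZSN": float(np.sum(P.sum(axis=0) ** 2) / nz),
        "ZP": float(nz / z.n_voxels),
    }
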