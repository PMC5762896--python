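"""Per-lesion feature extraction into a lesions x features table.

The feature vocabulary is fixed at 87 columns per lesion:

* 3 shape features on the (single, shared) mask: ``pre.solidity``,
  ``pre.extent``, ``pre.eccentricity``;
* 6 histogram features x 4 scans, from raw (unquantized) intensities;
* 4 GLCM features x 4 scans;
* 11 GLSZM features x 4 scans,

with texture computed on intensities quantized per scan to ``n_levels``
equal-width levels over the in-mask range.  Column names are
``"<scan>.<feature>"`` (e.g. ``post2.LZE``).  Lesions whose mask is
degenerate for a shape operation are skipped and logged rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import morphology, texture
from .errors import BcsRadiomicsError
from .phantom import SCAN_TAGS, Lesion

__all__ = [
    "HISTOGRAM_FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
    "feature_names",
    "feature_dictionary",
    "extract_features",
    "extract_table",
]

logger = logging.getLogger(__name__)

SHAPE_FEATURE_NAMES = ("solidity", "extent", "eccentricity")
HISTOGRAM_FEATURE_NAMES = ("minimum", "median", "mean", "variance", "skewness", "kurtosis")


def feature_names() -> list[str]:
    """The full ordered 87-column feature vocabulary."""
    names = [f"pre.{f}" for f in SHAPE_FEATURE_NAMES]
    for tag in SCAN_TAGS:
        names.extend(f"{tag}.{f}" for f in HISTOGRAM_FEATURE_NAMES)
    for tag in SCAN_TAGS:
        names.extend(f"{tag}.{f}" for f in texture.GLCM_FEATURE_NAMES)
    for tag in SCAN_TAGS:
        names.extend(f"{tag}.{f}" for f in texture.GLSZM_FEATURE_NAMES)
    return names


_FORMULAS = {
    "solidity": "n_foreground / n_voxels_in_convex_hull",
    "extent": "n_foreground / n_voxels_in_bounding_box",
    "eccentricity": "sqrt(1 - lambda_min/lambda_max) of voxel-cloud covariance",
    "minimum": "min(v)",
    "median": "median(v)",
    "mean": "mean(v)",
    "variance": "m2 (population)",
    "skewness": "m3 / m2^(3/2)",
    "kurtosis": "m4 / m2^2 (Pearson; normal = 3)",
    "energy": "sum p^2",
    "entropy": "-sum p log2 p",
    "homogeneity": "sum p / (1 + |i-j|)",
    "contrast": "sum p (i-j)^2",
    "SZE": "(1/Nz) sum P / j^2",
    "LZE": "(1/Nz) sum P j^2",
    "LIZE": "(1/Nz) sum P / i^2",
    "HIZE": "(1/Nz) sum P i^2",
    "LISZE": "(1/Nz) sum P / (i^2 j^2)",
    "HISZE": "(1/Nz) sum P i^2 / j^2",
    "LILZE": "(1/Nz) sum P j^2 / i^2",
    "HILZE": "(1/Nz) sum P i^2 j^2",
    "GLN": "(1/Nz) sum_i (sum_j P)^2",
    "ZSN": "(1/Nz) sum_j (sum_i P)^2",
    "ZP": "Nz / Np",
}


def feature_dictionary() -> dict[str, str]:
    """Map each feature column to a formula string (for run reports)."""
    return {name: _FORMULAS[name.split(".", 1)[1]] for name in feature_names()}


def extract_features(
    lesion: Lesion,
    n_levels: int = 16,
    glcm_distance: int = 1,
    glszm_connectivity: int = 26,
) -> dict[str, float]:
    """Compute all 87 features of one lesion."""
    out: dict[str, float] = {}
    shape = morphology.shape_features(lesion.mask, lesion.spacing)
    out["pre.solidity"] = shape.solidity
    out["pre.extent"] = shape.extent
    out["pre.eccentricity"] = shape.eccentricity

    for tag in SCAN_TAGS:
        vol = lesion.volumes[tag]
        if vol.shape != lesion.mask.shape:
            raise BcsRadiomicsError(
                f"{lesion.lesion_id}/{tag}: volume shape {vol.shape} != mask shape "
                f"{lesion.mask.shape}"
            )
        hist = morphology.histogram_features(vol, lesion.mask)
        for f in HISTOGRAM_FEATURE_NAMES:
            out[f"{tag}.{f}"] = getattr(hist, f)
        q = texture.quantize(vol, lesion.mask, n_levels=n_levels)
        glcm = texture.compute_glcm(q, distance=glcm_distance)
        for f, v in texture.glcm_features(glcm).items():
            out[f"{tag}.{f}"] = v
        glszm = texture.compute_glszm(q, connectivity=glszm_connectivity)
        for f, v in texture.glszm_features(glszm).items():
            out[f"{tag}.{f}"] = v
    return out


@dataclass(frozen=True)
class ExtractionResult:
    table: pd.DataFrame
    skipped: list[tuple[str, str]]  # (lesion_id, reason)


def extract_table(lesions, **kwargs) -> ExtractionResult:
    """Extract features for a cohort into a DataFrame (index = lesion_id).

    The returned table carries one row per successfully processed lesion
    plus a ``label`` column; lesions that fail a geometric precondition are
    recorded in ``skipped`` and excluded rather than imputed.
    """
    rows = {}
    labels = {}
    skipped: list[tuple[str, str]] = []
    for lesion in lesions:
        try:
            rows[lesion.lesion_id] = extract_features(lesion, **kwargs)
            labels[lesion.lesion_id] = lesion.label
        except BcsRadiomicsError as exc:
            logger.warning("skipping %s: %s", lesion.lesion_id, exc)
            skipped.append((lesion.lesion_id, str(exc)))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=feature_names())
    table.index.name = "lesion_id"
    table["label"] = pd.Series(labels)
    return ExtractionResult(table=table, skipped=skipped)
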