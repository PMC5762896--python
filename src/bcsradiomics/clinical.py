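"""Clinical characteristics of the reference HER2+ BCS cohort.

This module carries, as plain count tables, the published clinical profile
of a cohort of 109 women with HER2-overexpressing invasive breast cancer who
underwent breast conservation surgery (BCS) after preoperative DCE-MRI:
67 achieved clear margins at the first operation and 42 required surgical
re-excision.  The counts drive the cohort-comparison stage
(:func:`bcsradiomics.stats.cohort_summary`) and the headline epidemiological
rates the pipeline reports.

Group order everywhere is (no re-excision, re-excision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_SIZES",
    "CATEGORICAL_COUNTS",
    "REEXCISION_REASONS",
    "MULTIFOCAL_BY_REEXCISIONS",
    "records",
    "reexcision_rate",
    "residual_carcinoma_rate",
    "mastectomy_at_first_reexcision_rate",
    "multifocal_rates",
]

GROUP_SIZES = {0: 67, 1: 42}  # no re-excision, re-excision

# variable -> {category: (count in no-re-excision group, count in re-excision group)}
CATEGORICAL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "breast_density": {"1": (0, 1), "2": (5, 6), "3": (40, 28), "4": (18, 7), "NA": (4, 0)},
    "localization": {"no": (26, 5), "yes": (41, 37)},
    "localization_method": {"wire": (39, 35), "seed": (2, 2), "NA": (26, 5)},
    "bracket": {"no": (39, 34), "yes": (2, 3), "NA": (26, 5)},
    "invasive_type": {"IMC": (3, 6), "IDC": (64, 36)},
    "ER": {"negative": (17, 21), "positive": (49, 21), "borderline": (1, 0)},
    "PR": {"negative": (26, 27), "positive": (40, 15), "borderline": (1, 0)},
    "DCIS": {"no": (59, 29), "yes": (8, 13)},
    "multifocal_mri": {"no": (51, 25), "yes": (16, 17)},
}

# reason for re-excision -> (n, residual carcinoma at re-excision, mastectomy at
# first re-excision)
REEXCISION_REASONS: dict[str, tuple[int, int, int]] = {
    "ink_on_tumor": (25, 17, 11),
    "lt_1mm_margin": (13, 9, 4),
    "other": (4, 0, 0),
}

# number of re-excisions -> (group size, multifocal/multicentric on MRI)
MULTIFOCAL_BY_REEXCISIONS: dict[str, tuple[int, int]] = {
    "none": (67, 16),
    "one": (31, 17),
    "two_or_more": (11, 1),
}


def records(variables: list[str] | None = None) -> pd.DataFrame:
    """Expand the categorical count tables into one row per patient.

    Reconstruction is exact for categorical variables (the counts fully
    determine the per-patient values up to row order, which is fixed and
    deterministic).  Continuous variables are not reconstructable from
    summary statistics and are not included.
    """
    variables = variables or list(CATEGORICAL_COUNTS)
    cols: dict[str, list] = {"label": []}
    for g, n in GROUP_SIZES.items():
        cols["label"].extend([g] * n)
    for var in variables:
        table = CATEGORICAL_COUNTS[var]
        col: list[str] = []
        for gi in (0, 1):
            for cat, counts in table.items():
                col.extend([cat] * counts[gi])
            # NA-free variables may not cover the full group
            col.extend(["NA"] * (GROUP_SIZES[gi] - sum(c[gi] for c in table.values())))
        cols[var] = col
    return pd.DataFrame(cols)


def reexcision_rate() -> float:
    """Fraction of the cohort requiring re-excision after initial BCS, in percent."""
    return 100.0 * GROUP_SIZES[1] / sum(GROUP_SIZES.values())


def residual_carcinoma_rate() -> float:
    """Percent of re-excised patients with residual carcinoma in the re-excision
    specimen, pooled over all reasons for re-excision."""
    n = sum(v[0] for v in REEXCISION_REASONS.values())
    residual = sum(v[1] for v in REEXCISION_REASONS.values())
    return 100.0 * residual / n


def mastectomy_at_first_reexcision_rate() -> float:
    """Percent of re-excised patients converted to mastectomy at the first
    re-excision, pooled over all reasons."""
    n = sum(v[0] for v in REEXCISION_REASONS.values())
    mastectomy = sum(v[2] for v in REEXCISION_REASONS.values())
    return 100.0 * mastectomy / n


def multifocal_rates() -> dict[str, float]:
    """Percent multifocal/multicentric disease on MRI by number of re-excisions."""
    return {
        k: 100.0 * mf / n for k, (n, mf) in MULTIFOCAL_BY_REEXCISIONS.items()
    }
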