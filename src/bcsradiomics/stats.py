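"""Univariate screening of image features and clinical cohort comparisons.

Each feature is tested against the binary endpoint (surgical re-excision)
two ways, reported side by side with no reconciliation: Spearman rank
correlation (sign convention: positive Rs means larger values in the
re-excision group) and a two-sample t-test.  Categorical clinical variables
use Pearson chi-square without continuity correction, falling back to
Fisher's exact test for 2x2 tables with any expected count below 5.

No multiple-testing correction feeds selection; a Benjamini-Hochberg
adjusted column is emitted alongside as a clearly-labeled extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConstantFeatureError, ValidationError

__all__ = [
    "spearman_vs_endpoint",
    "two_sample_t",
    "categorical_test",
    "screen_features",
    "cohort_summary",
    "CohortTable",
]


def spearman_vs_endpoint(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman Rs between a feature and the binary endpoint, with p-value.

    Ties receive average ranks.  The p-value uses the t approximation with
    n - 2 df; ``exact=True`` (n <= 10 only) enumerates all pairings of the
    rank vectors for an exact permutation p-value.  A constant feature has
    no defined rank correlation and raises :class:`ConstantFeatureError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.unique(y).size < 2:
        raise ValidationError("both endpoint labels must be present")
    if np.ptp(x) == 0:
        raise ConstantFeatureError("feature is constant; Spearman Rs undefined")
    res = sps.spearmanr(x, y, alternative="two-sided")
    rs = float(res.statistic)
    if not exact:
        return rs, float(res.pvalue)
    if x.size > 10:
        raise ValidationError("exact permutation p-value only for n <= 10")
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(permutations(rx)))
    null = np.array([sps.pearsonr(p, ry).statistic for p in perms])
    p_exact = float(np.mean(np.abs(null) >= abs(rs) - 1e-12))
    return rs, p_exact


def two_sample_t(x0, x1, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default; Welch by flag)."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.ptp(x0) == 0 and np.ptp(x1) == 0 and x0[0] != x1[0]:
        raise ConstantFeatureError("zero pooled variance; t undefined")
    res = sps.ttest_ind(x0, x1, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def categorical_test(table) -> tuple[float, float, str]:
    """Chi-square (no continuity correction) or, for sparse 2x2, Fisher's exact.

    Returns (statistic, p, test_name); test_name records which test ran.
    For Fisher the statistic is the odds ratio.
    """
    table = np.asarray(table)
    if table.min() < 0 or not np.issubdtype(table.dtype, np.integer):
        raise ValidationError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("all-zero row or column")
    expected = sps.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p = sps.fisher_exact(table)
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2"


def screen_features(table: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """Univariate screen of every feature column against the endpoint.

    Returns one row per feature with Spearman Rs/p, t statistic/p, and a
    Benjamini-Hochberg adjusted Spearman p (``p_spearman_bh``, an extension
    column not used for feature selection).  Features that are constant are
    flagged in the ``note`` column with NaN statistics instead of silently
    propagating.
    """
    if label_col not in table.columns:
        raise ValidationError(f"missing label column {label_col!r}")
    y = table[label_col].to_numpy()
    rows = []
    for name in table.columns:
        if name == label_col:
            continue
        x = table[name].to_numpy(dtype=float)
        note = ""
        try:
            rs, p_s = spearman_vs_endpoint(x, y)
            t, p_t = two_sample_t(x[y == 0], x[y == 1])
        except ConstantFeatureError as exc:
            rs = p_s = t = p_t = float("nan")
            note = str(exc)
        rows.append(
            {"feature": name, "rs": rs, "p_spearman": p_s, "t_stat": t,
             "p_ttest": p_t, "note": note}
        )
    out = pd.DataFrame(rows)
    out["p_spearman_bh"] = _benjamini_hochberg(out["p_spearman"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return adj
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj


@dataclass(frozen=True)
class CohortTable:
    """Group-wise cohort characteristics with per-variable tests.

    ``categorical``: variable -> dict with counts per category per group,
    percentages (of group size, rounded to nearest integer), test name and
    p-value.  ``continuous``: variable -> per-group mean/sd and t-test p.
    ``derived``: headline rates in percent (e.g. the re-excision rate).
    """

    group_sizes: dict[int, int]
    categorical: dict[str, dict]
    continuous: dict[str, dict]
    derived: dict[str, float]


def cohort_summary(
    records: pd.DataFrame,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    label_col: str = "label",
) -> CohortTable:
    """Summarize per-patient records by outcome group, with tests.

    Categorical variables get a 2 x k count table (group x category, with
    per-group percentages rounded to integers) and a chi-square/Fisher
    p-value; continuous variables get mean +/- sd per group and a pooled
    t-test p-value.  The headline derived rate is the label prevalence
    (re-excision rate) in percent.
    """
    if label_col not in records.columns:
        raise ValidationError(f"missing label column {label_col!r}")
    categorical = categorical or []
    continuous = continuous or []
    for var in categorical + continuous:
        if var not in records.columns:
            raise ValidationError(f"unknown variable {var!r}")
    groups = sorted(records[label_col].unique())
    sizes = {int(g): int((records[label_col] == g).sum()) for g in groups}
    n_total = sum(sizes.values())

    cat_out: dict[str, dict] = {}
    for var in categorical:
        cats = sorted(records[var].dropna().unique())
        counts = np.array(
            [[int(((records[label_col] == g) & (records[var] == c)).sum()) for c in cats]
             for g in groups]
        )
        pct = {
            int(g): {c: round(100 * counts[gi, ci] / max(sizes[int(g)], 1))
                     for ci, c in enumerate(cats)}
            for gi, g in enumerate(groups)
        }
        stat, p, test_name = categorical_test(counts)
        cat_out[var] = {
            "categories": cats,
            "counts": counts,
            "percent": pct,
            "statistic": stat,
            "p": p,
            "test": test_name,
        }

    cont_out: dict[str, dict] = {}
    for var in continuous:
        vals = {int(g): records.loc[records[label_col] == g, var].dropna().to_numpy()
                for g in groups}
        t, p = two_sample_t(vals[int(groups[0])], vals[int(groups[1])]) \
            if len(groups) == 2 else (float("nan"), float("nan"))
        cont_out[var] = {
            "mean": {g: float(v.mean()) for g, v in vals.items()},
            "sd": {g: float(v.std(ddof=1)) for g, v in vals.items()},
            "t_stat": t,
            "p": p,
        }

    derived = {}
    if 1 in sizes:
        derived["reexcision_rate_pct"] = 100.0 * sizes[1] / n_total
    return CohortTable(
        group_sizes=sizes, categorical=cat_out, continuous=cont_out, derived=derived
    )
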