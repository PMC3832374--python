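"""Method-comparison statistics: group summaries, percentage reduction,
paired t-test and Bland-Altman agreement.

Conventions:

* differences are method A - method B (here: optical - MRI);
* the standard deviation of differences is the sample (n-1) SD;
* limits of agreement are ``bias +/- 2 * SD`` (the +/-2 SD convention, not
  1.96 SD);
* report tables round GFR to 2 d.p. and agreement statistics to 1 d.p.;
  raw full precision is always retained in the returned objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import ComparisonStats, ValidationError

__all__ = [
    "group_summary",
    "percent_reduction",
    "paired_ttest",
    "bland_altman",
    "compare_methods",
]


def group_summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a sample SD")
    return float(values.mean()), float(values.std(ddof=1))


def percent_reduction(mean_ref: float, mean_test: float) -> float:
    """How much lower ``mean_test`` is than ``mean_ref``, in percent."""
    if mean_ref <= 0:
        raise ValidationError("reference mean must be positive")
    return 100.0 * (1.0 - mean_test / mean_ref)


def paired_ttest(a, b) -> tuple[float, int, float, bool]:
    """Two-sided paired t-test on per-subject differences.

    Returns ``(t, df, p, degenerate)``; ``degenerate`` is True when the
    differences have zero variance (the statistic is then undefined and
    ``t``/``p`` are NaN rather than raising).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("need two equal-length vectors of >= 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("pairs must be finite")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return np.nan, len(d) - 1, np.nan, True
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(d) - 1, float(res.pvalue), False


def bland_altman(a, b) -> ComparisonStats:
    """Bland-Altman agreement between paired measurements ``a`` and ``b``.

    Computes per-pair differences ``d_i = a_i - b_i`` and means
    ``(a_i + b_i)/2`` (the plot coordinates), the bias (mean difference),
    the sample SD of differences, limits of agreement ``bias +/- 2 SD``
    and the count of pairs outside them, plus the paired t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("need two equal-length vectors of >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 2.0 * sd, bias + 2.0 * sd)
    outside = int(np.sum((d < loa[0]) | (d > loa[1])))
    t, df, p, degen = paired_ttest(a, b)
    return ComparisonStats(n=len(d), bias=bias, sd_diff=sd, loa=loa,
                           n_outside=outside, t_stat=t, df=df, p_value=p,
                           degenerate=degen, means=(a + b) / 2.0, diffs=d)


def compare_methods(table: pd.DataFrame,
                    col_a: str = "gfr_optical",
                    col_b: str = "gfr_mri",
                    group_col: str = "group",
                    ref_group: str = "SD",
                    test_group: str = "UNX") -> dict:
    """Full comparison of two GFR methods on a per-animal table.

    For each group: mean and SD per method and the within-group paired
    test between methods.  Across groups: the percentage reduction of the
    test group relative to the reference group, per method.  Across all
    animals: Bland-Altman agreement between methods.

    Returns a plain dict (JSON-serialisable except for the embedded
    :class:`~renogfr.io_types.ComparisonStats`).
    """
    for col in (col_a, col_b, group_col):
        if col not in table.columns:
            raise ValidationError(f"table lacks column {col!r}")
    out: dict = {"groups": {}}
    for g, sub in table.groupby(group_col, sort=False):
        mean_a, sd_a = group_summary(sub[col_a])
        mean_b, sd_b = group_summary(sub[col_b])
        t, df, p, degen = paired_ttest(sub[col_a], sub[col_b])
        out["groups"][g] = {
            col_a: {"mean": mean_a, "sd": sd_a},
            col_b: {"mean": mean_b, "sd": sd_b},
            "paired_t": {"t": t, "df": df, "p": p, "degenerate": degen},
            "n": len(sub),
        }
    if ref_group in out["groups"] and test_group in out["groups"]:
        out["pct_reduction"] = {
            method: percent_reduction(
                out["groups"][ref_group][method]["mean"],
                out["groups"][test_group][method]["mean"])
            for method in (col_a, col_b)
        }
    out["bland_altman"] = bland_altman(table[col_a].to_numpy(),
                                       table[col_b].to_numpy())
    return out
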