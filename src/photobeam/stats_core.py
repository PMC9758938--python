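"""Statistics used by the behavioural analyses.

Pearson correlation and one-way ANOVA are delegated to scipy; the
post-hoc linear-trend contrast — the test used to detect habituation
across ordered recording epochs — is implemented here.

The trend test is the classical orthogonal linear contrast on a one-way
layout: with equally spaced epoch scores the contrast coefficients are the
centered scores, the contrast F uses the pooled within-group mean square on
(1, N - k) degrees of freedom, and the reported slope is the change in
group mean per unit epoch.  R² is the proportion of the *between-group*
sum of squares explained by the linear contrast (the convention of the
commercial "post test for trend", under which the published values near 1
mean "the between-epoch differences are almost perfectly linear"), not the
proportion of total variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .monitor_data import UsageError, ValidationError

__all__ = ["TrendResult", "pearson", "anova_oneway", "linear_trend"]


@dataclass(frozen=True)
class TrendResult:
    """Result of the post-hoc linear-trend contrast."""

    slope: float    # change in group mean per unit epoch score
    R2: float       # contrast SS / between-group SS
    p: float        # two-sided p of the contrast F(1, df_within)
    F: float
    df: tuple       # (1, df_within)


def pearson(x, y):
    """Product-moment correlation with two-sided t-test p-value.

    Returns ``(r, p, n)``; requires n >= 3 and non-zero variance in both
    variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise UsageError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise UsageError("pearson requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("pearson undefined: zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def anova_oneway(groups: Sequence):
    """Classical one-way ANOVA; returns ``(F, p, df_between, df_within)``."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise UsageError("anova_oneway requires at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise UsageError("every group needs at least 2 observations")
    ns = np.array([len(g) for g in groups])
    res = sps.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = int(ns.sum()) - len(groups)
    return float(res.statistic), float(res.pvalue), df_between, df_within


def linear_trend(groups: Sequence, scores: Sequence = None) -> TrendResult:
    """Post-hoc test for linear trend across ordered group means.

    ``groups`` are the ordered samples (one per epoch); ``scores`` the
    epoch indices (default ``0, 1, ..., k-1``; must be equally spaced).
    The contrast coefficients are the centered scores; the slope is
    reported per unit score so that epoch indices give a per-epoch slope.
    With between-group SS of zero the trend is degenerate: slope 0, R² 0 by
    convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise UsageError("linear_trend requires at least 3 ordered groups")
    if any(len(g) < 2 for g in groups):
        raise UsageError("every group needs at least 2 observations")
    if scores is None:
        scores = np.arange(k, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != k:
        raise UsageError("scores must match the number of groups")
    steps = np.diff(scores)
    if not np.allclose(steps, steps[0]) or steps[0] <= 0:
        raise UsageError("scores must be strictly increasing and equally spaced")

    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    N = ns.sum()

    c = scores - scores.mean()            # centered-score contrast
    L = float(np.dot(c, means))           # contrast estimate
    slope = L / float(np.dot(c, c))       # OLS slope of means on scores
    ss_contrast = L ** 2 / float(np.sum(c ** 2 / ns))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_within = int(N) - k
    ms_within = ss_within / df_within
    if ss_between <= 0:
        return TrendResult(slope=0.0, R2=0.0, p=1.0, F=0.0,
                           df=(1, df_within))
    if ms_within <= 0:  # perfectly separated groups
        return TrendResult(slope=float(slope),
                           R2=float(ss_contrast / ss_between),
                           p=0.0 if ss_contrast > 0 else 1.0,
                           F=float("inf") if ss_contrast > 0 else 0.0,
                           df=(1, df_within))
    F = ss_contrast / ms_within
    p = float(sps.f.sf(F, 1, df_within))
    return TrendResult(slope=float(slope), R2=float(ss_contrast / ss_between),
                       p=p, F=float(F), df=(1, df_within))
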