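"""Cohort-level association statistics and onset-group classification.

Age at onset (AO) and age at death (AD) enter regressions on the natural-log
scale; standalone Pearson correlations against AO/AD are reported on the raw
scale.  Onset groups come from the standardized residuals of log-AO given
the reference CAG length: residual < -0.5 means earlier-than-expected onset,
residual > 0.5 later-than-expected, otherwise as expected.  Two-group
comparisons use the Wilcoxon rank-sum test and three or more groups the
Kruskal-Wallis test, both with mid-rank tie handling and asymptotic p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .trace_io import SubjectRecord

__all__ = [
    "AssociationResult",
    "OnsetClassification",
    "GroupTestResult",
    "ZeroVarianceError",
    "simple_regression",
    "residualize",
    "classify_onset",
    "group_tests",
    "EARLIER",
    "AS_EXPECTED",
    "LATER",
]

EARLIER = "earlier"
AS_EXPECTED = "as_expected"
LATER = "later"


class ZeroVarianceError(ValueError):
    """The predictor has no variance; the regression slope is undefined."""


@dataclass(frozen=True)
class AssociationResult:
    """Simple-regression summary: slope, intercept, Pearson r, adjusted R2, slope p."""

    n: int
    slope: float
    intercept: float
    r: float
    r2_adj: float
    p_slope: float


@dataclass(frozen=True)
class OnsetClassification:
    subject_id: str
    std_residual: float
    group: str


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]


def _complete_pairs(y: Sequence[float], x: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    if ya.shape != xa.shape:
        raise ValueError("y and x must have equal length")
    mask = np.isfinite(ya) & np.isfinite(xa)
    return ya[mask], xa[mask], mask


def simple_regression(y: Sequence[float], x: Sequence[float], log_y: bool = False) -> AssociationResult:
    """OLS of y (optionally ln y) on x with pairwise deletion of missing values.

    Pearson r is reported between the actually regressed variables; the slope
    p-value is two-sided from the t distribution with n - 2 df, and
    ``r2_adj = 1 - (1 - r^2)(n - 1)/(n - 2)``.
    """
    yy, xx, _ = _complete_pairs(y, x)
    n = len(yy)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, have {n}")
    if np.ptp(xx) == 0:
        raise ZeroVarianceError("predictor x has zero variance")
    if log_y:
        if np.any(yy <= 0):
            raise ValueError("log transform requires positive y values")
        yy = np.log(yy)
    res = stats.linregress(xx, yy)
    r2 = res.rvalue**2
    return AssociationResult(
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2_adj=float(1 - (1 - r2) * (n - 1) / (n - 2)),
        p_slope=float(res.pvalue),
    )


def residualize(y: Sequence[float], x: Sequence[float], log_y: bool = False) -> np.ndarray:
    """OLS residuals of y (or ln y) given x, in input order; missing pairs stay NaN."""
    yy, xx, mask = _complete_pairs(y, x)
    fit = simple_regression(yy, xx, log_y=log_y)
    values = np.log(yy) if log_y else yy
    out = np.full(mask.shape, np.nan)
    out[mask] = values - (fit.intercept + fit.slope * xx)
    return out


def classify_onset(
    subjects: Iterable[SubjectRecord], use_effective_onset: bool = True
) -> list[OnsetClassification]:
    """Onset groups from standardized residuals of ln(AO) on reference CAG.

    Residuals are standardized by their sample standard deviation (ddof=1),
    giving mean 0 and unit variance across the cohort.  Subjects with
    residual < -0.5 had earlier-than-expected onset, > 0.5 later, otherwise
    as expected.
    """
    subjects = list(subjects)
    onsets = [
        (s.effective_age_onset if use_effective_onset else s.age_onset) for s in subjects
    ]
    if any(a is None for a in onsets):
        missing = [s.subject_id for s, a in zip(subjects, onsets) if a is None]
        raise ValueError(f"age at onset missing for subjects: {missing}")
    cags = [s.cag_ref for s in subjects]
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to classify onset")
    resid = residualize(onsets, cags, log_y=True)
    sd = resid.std(ddof=1)
    z = resid / sd if sd > 0 else np.zeros_like(resid)  # all exactly on the line
    out = []
    for s, zi in zip(subjects, z):
        group = EARLIER if zi < -0.5 else LATER if zi > 0.5 else AS_EXPECTED
        out.append(OnsetClassification(subject_id=s.subject_id, std_residual=float(zi), group=group))
    return out


def group_tests(values: Sequence[float], groups: Sequence[str]) -> GroupTestResult:
    """Nonparametric comparison of ``values`` across ``groups``.

    Two groups: Wilcoxon rank-sum (Mann-Whitney U, asymptotic with mid-rank
    tie correction and continuity correction), two-sided.  Three or more:
    Kruskal-Wallis.  Degenerate inputs where every observation is identical
    give p = 1 rather than an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must have equal length")
    names = list(dict.fromkeys(labels.tolist()))  # before dropping missing values
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    parts = {name: values[labels == name] for name in names}
    for name, part in parts.items():
        if len(part) == 0:
            raise ValueError(f"group {name!r} has no observations")
    if len(names) < 2:
        raise ValueError("need at least 2 non-empty groups")
    sizes = {name: int(len(part)) for name, part in parts.items()}
    if np.ptp(values) == 0:
        # all observations tied: no evidence of any shift under mid-ranks
        if len(names) == 2:
            n1, n2 = (len(parts[n]) for n in names)
            return GroupTestResult("wilcoxon_rank_sum", n1 * n2 / 2, 1.0, sizes)
        return GroupTestResult("kruskal_wallis", 0.0, 1.0, sizes)
    if len(names) == 2:
        res = stats.mannwhitneyu(
            parts[names[0]], parts[names[1]], alternative="two-sided", method="asymptotic"
        )
        return GroupTestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), sizes)
    res = stats.kruskal(*parts.values())
    return GroupTestResult("kruskal_wallis", float(res.statistic), float(res.pvalue), sizes)
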