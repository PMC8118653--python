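"""Per-subject expansion trajectories: expansion rate and extrapolated onset index.

Each subject's expansion index (EI) is regressed on age over their 2-3 visits
by ordinary least squares.  The slope is the expansion rate (ER, EI units per
year); the intercept is a theoretical EI at birth; evaluating the fitted line
at the subject's age at motor onset gives the (extrapolated) expansion index
at onset, EI-AO.  A fit is valid only with at least two visits at distinct
ages — repeated sampling at a single age leaves the slope undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trace_io import SubjectRecord

__all__ = [
    "TrajectoryFit",
    "fit_subject_trajectory",
    "extrapolate_ei_at_onset",
    "cohort_trajectories",
    "trajectory_summary",
    "visit_deltas",
    "fits_frame",
]


@dataclass(frozen=True)
class TrajectoryFit:
    """OLS line of EI on age for one subject.

    ``ei_ao`` is ``intercept + slope * age_onset`` using the subject's
    effective onset age; absent when the fit is invalid or onset is unknown.
    """

    subject_id: str
    n_visits: int
    valid: bool
    slope: float | None = None
    intercept: float | None = None
    ei_ao: float | None = None


def fit_subject_trajectory(
    ages: Sequence[float], eis: Sequence[float], subject_id: str = ""
) -> TrajectoryFit:
    """Least-squares line of EI on age; degenerate inputs give an invalid fit.

    With exactly two visits this reduces to the two-point slope.  Fewer than
    two distinct ages (including the single-visit case) yields
    ``valid=False`` with slope and intercept absent, not an exception.
    """
    if len(ages) != len(eis):
        raise ValueError("ages and eis must have equal length")
    if len(ages) == 0:
        raise ValueError("at least one visit is required")
    x = np.asarray(ages, dtype=float)
    y = np.asarray(eis, dtype=float)
    if len(set(x.tolist())) < 2:
        return TrajectoryFit(subject_id=subject_id, n_visits=len(x), valid=False)
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.dot(x - xbar, y - ybar) / np.dot(x - xbar, x - xbar))
    intercept = float(ybar - slope * xbar)
    return TrajectoryFit(
        subject_id=subject_id, n_visits=len(x), valid=True, slope=slope, intercept=intercept
    )


def extrapolate_ei_at_onset(fit: TrajectoryFit, age_onset: float) -> float | None:
    """Fitted EI at the age at onset; ``None`` for an invalid fit."""
    if not fit.valid:
        return None
    if not age_onset > 0:
        raise ValueError(f"age at onset must be positive, got {age_onset}")
    return fit.intercept + fit.slope * age_onset


def cohort_trajectories(subjects: Iterable[SubjectRecord]) -> list[TrajectoryFit]:
    """One trajectory fit per subject, with EI-AO filled in where onset is known."""
    fits = []
    for s in subjects:
        fit = fit_subject_trajectory([v.age for v in s.visits], [v.ei for v in s.visits], s.subject_id)
        onset = s.effective_age_onset
        if fit.valid and onset is not None:
            fit = TrajectoryFit(
                subject_id=fit.subject_id,
                n_visits=fit.n_visits,
                valid=True,
                slope=fit.slope,
                intercept=fit.intercept,
                ei_ao=extrapolate_ei_at_onset(fit, onset),
            )
        fits.append(fit)
    return fits


def _stats(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {
        "n": len(arr),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else math.nan,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def trajectory_summary(fits: Iterable[TrajectoryFit]) -> dict[str, dict[str, float]]:
    """Mean/SD/range of ER and EI-AO over valid fits."""
    fits = list(fits)
    ers = [f.slope for f in fits if f.valid]
    eiaos = [f.ei_ao for f in fits if f.valid and f.ei_ao is not None]
    out: dict[str, dict[str, float]] = {}
    if ers:
        out["er"] = _stats(ers)
    if eiaos:
        out["ei_ao"] = _stats(eiaos)
    out["n_valid"] = sum(f.valid for f in fits)
    out["n_invalid"] = sum(not f.valid for f in fits)
    return out


def visit_deltas(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Consecutive-visit age gaps, EI changes, and pairwise rates.

    One row per consecutive visit pair (transition 1 is visit1->visit2).
    The pairwise rate is NaN when the two visits share one age.
    """
    rows = []
    for s in subjects:
        for k, (a, b) in enumerate(zip(s.visits, s.visits[1:]), start=1):
            dage = b.age - a.age
            dei = b.ei - a.ei
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "transition": k,
                    "delta_age": dage,
                    "delta_ei": dei,
                    "rate": dei / dage if dage > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def fits_frame(subjects: Iterable[SubjectRecord], fits: Iterable[TrajectoryFit]) -> pd.DataFrame:
    """Per-subject table (id, cag_ref, slope, intercept, ei_ao, valid) for export."""
    rows = []
    for s, f in zip(subjects, fits):
        rows.append(
            {
                "subject_id": s.subject_id,
                "cag_ref": s.cag_ref,
                "n_visits": f.n_visits,
                "valid": f.valid,
                "slope": f.slope,
                "intercept": f.intercept,
                "ei_ao": f.ei_ao,
            }
        )
    return pd.DataFrame(rows)
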