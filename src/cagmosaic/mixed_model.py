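"""Random-intercept mixed model of log expansion index on age and CAG.

The within-subject model for visit j of subject i is

    ln EI_ij = b0 + b_age (age_ij - mean_age) + b_cag (CAG_i - mean_cag)
             + b_int (age_ij - mean_age)(CAG_i - mean_cag) [+ b_sex male_i]
             + u_i + e_ij,      u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

fitted by restricted maximum likelihood (REML).  Age and CAG are mean-centered
over observations, so exp(b0) is the predicted EI of a subject with the
cohort's average age and repeat length.  Predicted age-trajectories come from
the fixed-effects surface with the random intercept set to zero and are
back-transformed to the EI scale.

Implementation notes: the REML fit is delegated to statsmodels ``MixedLM``;
p-values use a t reference with residual degrees of freedom (n_obs minus the
number of fixed effects) — the estimates, standard errors and t-values that
the model is summarized by do not depend on that choice.  A random-intercept
variance estimated at (or under) 1e-8 times the residual variance is flagged
``boundary`` rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .trace_io import MALE, SubjectRecord

__all__ = [
    "FixedEffect",
    "LmmFit",
    "TrajectoryCurve",
    "fit_lmm",
    "predict_ei",
    "predict_trajectories",
    "long_format",
]


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    t_value: float
    p_value: float


@dataclass
class LmmFit:
    """REML fit summary: fixed effects, variance components, centering constants."""

    fixed_effects: dict[str, FixedEffect]
    random_intercept_sd: float
    residual_sd: float
    mean_age: float
    mean_cag: float
    n_obs: int
    n_groups: int
    converged: bool = True
    boundary: bool = False
    message: str = ""


@dataclass
class TrajectoryCurve:
    """Back-transformed predicted EI over an age grid for one CAG length."""

    cag: int
    ages: np.ndarray
    predicted_ei: np.ndarray
    male: int = 0


_TERMS = ("intercept", "age", "cag", "age:cag", "sex")


def long_format(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format visit table (subject, sex, cag, age, ei) from subject records."""
    rows = [
        {"subject": s.subject_id, "sex": s.sex, "cag": s.cag_ref, "age": v.age, "ei": v.ei}
        for s in subjects
        for v in s.visits
    ]
    return pd.DataFrame(rows)


def fit_lmm(
    data: pd.DataFrame,
    include_sex: bool | None = None,
    centering: tuple[float, float] | None = None,
) -> LmmFit:
    """Fit the random-intercept REML model of ln(EI) to long-format visit data.

    Parameters
    ----------
    data : DataFrame with columns ``subject``, ``age``, ``cag``, ``ei`` and
        optionally ``sex`` ("male"/"female").
    include_sex : force the sex term in or out; by default it is included
        exactly when a ``sex`` column with known values is present.  Sex is
        coded as an indicator for male with female as reference.
    centering : explicit (mean_age, mean_cag) to center on; defaults to the
        observation-level sample means.  Because the model has an age x CAG
        interaction, the main-effect coefficients are specific to the
        centering constants.
    """
    required = {"subject", "age", "cag", "ei"}
    if missing := required - set(data.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = data.reset_index(drop=True).copy()
    if np.any(~(df["ei"] > 0)):
        raise ValueError("all EI values must be positive for the log transform")
    counts = df.groupby("subject").size()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 observations each")
    if include_sex is None:
        include_sex = "sex" in df.columns and df["sex"].isin(("male", "female")).all()
    if centering is None:
        mean_age = float(df["age"].mean())
        mean_cag = float(df["cag"].mean())
    else:
        mean_age, mean_cag = float(centering[0]), float(centering[1])
    y = np.log(df["ei"].to_numpy(dtype=float))
    age_c = df["age"].to_numpy(dtype=float) - mean_age
    cag_c = df["cag"].to_numpy(dtype=float) - mean_cag
    cols = {"intercept": np.ones(len(df)), "age": age_c, "cag": cag_c, "age:cag": age_c * cag_c}
    if include_sex:
        cols["sex"] = (df["sex"] == MALE).to_numpy(dtype=float)
    exog = pd.DataFrame(cols)
    model = MixedLM(endog=y, exog=exog, groups=df["subject"].to_numpy())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=True)
    message = "; ".join(str(w.message) for w in caught)
    p = exog.shape[1]
    df_resid = len(df) - p
    fixed: dict[str, FixedEffect] = {}
    for i, term in enumerate(exog.columns):
        est = float(result.fe_params.iloc[i])
        se = float(result.bse_fe.iloc[i])
        t = est / se
        fixed[term] = FixedEffect(est, se, t, float(2 * sps.t.sf(abs(t), df_resid)))
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    resid_var = float(result.scale)
    return LmmFit(
        fixed_effects=fixed,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(resid_var)),
        mean_age=mean_age,
        mean_cag=mean_cag,
        n_obs=len(df),
        n_groups=int(len(counts)),
        converged=bool(result.converged),
        boundary=re_var <= 1e-8 * resid_var,
        message=message,
    )


def predict_ei(fit: LmmFit, age: float | np.ndarray, cag: float, male: int = 0) -> np.ndarray:
    """Population-level predicted EI (random intercept at zero), back-transformed."""
    fe = fit.fixed_effects
    age = np.asarray(age, dtype=float)
    eta = (
        fe["intercept"].estimate
        + fe["age"].estimate * (age - fit.mean_age)
        + fe["cag"].estimate * (cag - fit.mean_cag)
        + fe["age:cag"].estimate * (age - fit.mean_age) * (cag - fit.mean_cag)
    )
    if "sex" in fe:
        eta = eta + fe["sex"].estimate * male
    return np.exp(eta)


def predict_trajectories(
    fit: LmmFit,
    cag_values: list[int],
    age_ranges: dict[int, tuple[float, float]] | None = None,
    subjects: list[SubjectRecord] | None = None,
    n_points: int = 50,
    male: int = 0,
) -> list[TrajectoryCurve]:
    """Predicted EI-vs-age curves, one per CAG length.

    Each curve spans the observed age interval for that CAG — supplied via
    ``age_ranges`` or derived from ``subjects`` — so predictions stay inside
    the cohort's support.  A CAG with no observed interval is skipped with a
    warning.
    """
    if age_ranges is None:
        if subjects is None:
            raise ValueError("supply age_ranges or subjects to derive them from")
        age_ranges = {}
        for s in subjects:
            ages = [v.age for v in s.visits]
            if not ages:
                continue
            lo, hi = age_ranges.get(s.cag_ref, (min(ages), max(ages)))
            age_ranges[s.cag_ref] = (min(lo, min(ages)), max(hi, max(ages)))
    curves = []
    for cag in cag_values:
        if cag not in age_ranges:
            warnings.warn(f"CAG {cag} outside the fitted support; no age interval available")
            continue
        lo, hi = age_ranges[cag]
        ages = np.linspace(lo, hi, n_points)
        curves.append(TrajectoryCurve(cag=cag, ages=ages, predicted_ei=predict_ei(fit, ages, cag, male), male=male))
    return curves
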