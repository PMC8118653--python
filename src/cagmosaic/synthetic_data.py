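"""Synthetic electropherograms and longitudinal cohorts with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`simulate_trace` builds a heterozygous fragment trace with the anatomy
  seen in real HTT repeat PCR profiles — a normal-allele cluster, a dominant
  expanded-allele main peak, left-hand stutter ladders, right-hand somatic
  expansion peaks at 3-bp spacing with geometrically decaying heights, plus
  optional size jitter and spurious off-ladder noise peaks.  The expected
  expansion index is available in closed form from the parameters alone, so
  the generator doubles as an oracle for the EI pipeline.
* :func:`simulate_cohort` draws longitudinal cohorts exactly from the
  random-intercept log-linear model (subject random intercept, residual noise,
  centered age and CAG with interaction, optional sex shift), so mixed-model
  estimates can be checked against known coefficients.

Geometric decay of the expansion-peak ratios is a modelling convenience that
reproduces the qualitative trace shape (mass concentrated at the main peak,
a tail that grows with CAG); it is not claimed to be the biological truth.
Both generators take an explicit seed and use a private random stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import FEMALE, MALE, FragmentTrace, Peak, SubjectRecord, VisitRecord

__all__ = [
    "TraceSimParams",
    "SimulatedTrace",
    "CohortSimParams",
    "expected_ei",
    "simulate_trace",
    "simulate_cohort",
]

#: Fragment size of a pure-CAG allele: constant flank plus 3 bp per repeat.
FLANK_BP = 87.0


@dataclass(frozen=True)
class TraceSimParams:
    """Ground-truth parameters of a synthetic fragment trace.

    Right-hand expansion peaks at offset i >= 1 have height ratio
    ``expansion_scale * expansion_decay**(i - 1)`` relative to the main peak;
    stutter ratios apply symmetrically to the left of the main and normal
    peaks.  ``noise_peak_rate`` is the expected count of spurious peaks
    placed off the 3-bp ladder (1.2-1.8 bp from the nearest rung).
    """

    cag_normal: int = 17
    cag_ref: int = 44
    main_height: float = 5000.0
    expansion_scale: float = 0.45
    expansion_decay: float = 0.55
    max_offset: int = 8
    stutter_ratios: tuple[float, ...] = (0.40, 0.18, 0.07)
    normal_height_factor: float = 1.15
    size_jitter_sd: float = 0.0
    noise_peak_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.expansion_decay < 1:
            raise ValueError(f"expansion_decay must be in (0, 1), got {self.expansion_decay}")
        if self.expansion_scale < 0:
            raise ValueError("expansion_scale must be non-negative")
        if self.expansion_scale > 1:
            raise ValueError(
                "expansion_scale > 1 would make the first expansion peak taller than the main peak"
            )
        if self.cag_ref < 36:
            raise ValueError("cag_ref must be an expanded allele (>= 36)")
        if not 0 < self.cag_normal < self.cag_ref:
            raise ValueError("cag_normal must be positive and below cag_ref")
        if self.max_offset < 0 or self.size_jitter_sd < 0 or self.noise_peak_rate < 0:
            raise ValueError("max_offset, size_jitter_sd and noise_peak_rate must be non-negative")

    @property
    def main_size_bp(self) -> float:
        """Nominal fragment size of the main expanded-allele peak (anchor for calibration)."""
        return FLANK_BP + 3.0 * self.cag_ref

    def right_ratio(self, offset: int) -> float:
        return self.expansion_scale * self.expansion_decay ** (offset - 1)


def expected_ei(params: TraceSimParams, threshold: float = 0.03) -> float:
    """Closed-form EI implied by the parameters at a given relative threshold."""
    return sum(
        params.right_ratio(i) * i
        for i in range(1, params.max_offset + 1)
        if params.right_ratio(i) >= threshold
    )


@dataclass
class SimulatedTrace:
    """A simulated trace plus its ground truth.

    ``true_repeats`` aligns with ``trace.peaks`` (None marks noise peaks that
    belong to no ladder rung).
    """

    trace: FragmentTrace
    true_repeats: tuple[int | None, ...]
    expected_ei: float
    params: TraceSimParams


def _rung_size(cag: int) -> float:
    return FLANK_BP + 3.0 * cag


def simulate_trace(params: TraceSimParams, seed: int | None = None) -> SimulatedTrace:
    """Generate one synthetic electropherogram; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    entries: list[tuple[float, float, int | None]] = []  # (size, height, true repeat)

    def ladder(cag: int, height: float) -> None:
        entries.append((_rung_size(cag), height, cag))

    normal_h = params.normal_height_factor * params.main_height
    ladder(params.cag_normal, normal_h)
    for k, ratio in enumerate(params.stutter_ratios, start=1):
        if params.cag_normal - k > 0:
            ladder(params.cag_normal - k, ratio * normal_h)
    ladder(params.cag_ref, params.main_height)
    for k, ratio in enumerate(params.stutter_ratios, start=1):
        if params.cag_normal < params.cag_ref - k:
            ladder(params.cag_ref - k, ratio * params.main_height)
    for i in range(1, params.max_offset + 1):
        h = params.right_ratio(i) * params.main_height
        if h > 0:
            ladder(params.cag_ref + i, h)

    if params.size_jitter_sd > 0:
        # capillary sizing error is bounded in practice; truncate at 2.5 SD so a
        # jitter SD <= 0.4 bp can never push a peak off the 1.0 bp ladder tolerance
        sd = params.size_jitter_sd
        jitter = np.clip(rng.normal(0.0, sd, size=len(entries)), -2.5 * sd, 2.5 * sd)
        entries = [(size + j, h, cag) for (size, h, cag), j in zip(entries, jitter)]
    n_noise = rng.poisson(params.noise_peak_rate) if params.noise_peak_rate > 0 else 0
    lo = _rung_size(max(params.cag_normal - len(params.stutter_ratios), 1))
    hi = _rung_size(params.cag_ref + params.max_offset)
    for _ in range(n_noise):
        rung = rng.integers(round((lo - FLANK_BP) / 3), round((hi - FLANK_BP) / 3) + 1)
        shift = rng.uniform(1.2, 1.8) * rng.choice([-1.0, 1.0])
        entries.append((_rung_size(int(rung)) + shift, rng.uniform(0.02, 0.5) * params.main_height, None))

    entries.sort(key=lambda e: e[0])
    peaks = [Peak(size_bp=size, height=h) for size, h, _ in entries]
    trace = FragmentTrace(sample_id=f"sim-cag{params.cag_ref}", peaks=peaks)
    return SimulatedTrace(
        trace=trace,
        true_repeats=tuple(cag for _, _, cag in entries),
        expected_ei=expected_ei(params),
        params=params,
    )


# ---------------------------------------------------------------------------
# Longitudinal cohorts

#: Reference-CAG frequencies mirroring the longitudinal cohort (39-54 repeats).
_DEFAULT_CAG_WEIGHTS = {
    39: 1, 40: 2, 41: 2, 42: 11, 43: 5, 44: 11, 45: 3, 46: 4,
    47: 1, 48: 2, 49: 3, 50: 1, 52: 2, 53: 1, 54: 1,
}


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the longitudinal cohort generator.

    Defaults emulate the study cohort: 50 subjects, roughly a quarter with a
    third visit, first sampling at 37.8 +/- 12.6 years (clipped to 20-76),
    inter-visit gaps of 12 +/- 4.9 then 6.2 +/- 5.2 years, reference CAG
    drawn 39-54 with the cohort's frequencies, 38% male, and log-EI model
    coefficients matching the fitted blood model (intercept -0.603, age
    0.028/yr, CAG 0.276/repeat, interaction 0.002, male shift 0.028; random
    intercept SD 0.258, residual SD 0.095; centering at 44.6 y / 44.7 CAG).
    """

    n_subjects: int = 50
    third_visit_prob: float = 0.24
    beta: tuple[float, float, float, float, float] = (-0.603, 0.028, 0.276, 0.002, 0.028)
    sigma_u: float = 0.258
    sigma_e: float = 0.095
    mean_age: float = 44.6
    mean_cag: float = 44.7
    cag_weights: tuple[tuple[int, float], ...] = tuple(_DEFAULT_CAG_WEIGHTS.items())
    first_age_mean: float = 37.8
    first_age_sd: float = 12.6
    first_age_range: tuple[float, float] = (20.0, 76.0)
    gap_means: tuple[float, float] = (12.0, 6.2)
    gap_sds: tuple[float, float] = (4.9, 5.2)
    min_gap: float = 1.0
    male_prob: float = 0.38

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0 <= self.third_visit_prob <= 1:
            raise ValueError("third_visit_prob must be in [0, 1]")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")


def simulate_cohort(params: CohortSimParams, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a longitudinal cohort exactly from the random-intercept log-linear model."""
    rng = np.random.default_rng(seed)
    b0, b_age, b_cag, b_int, b_sex = params.beta
    cags = np.array([c for c, _ in params.cag_weights])
    weights = np.array([w for _, w in params.cag_weights], dtype=float)
    weights /= weights.sum()
    subjects = []
    for i in range(params.n_subjects):
        cag = int(rng.choice(cags, p=weights))
        male = rng.random() < params.male_prob
        n_visits = 3 if rng.random() < params.third_visit_prob else 2
        age = float(
            np.clip(rng.normal(params.first_age_mean, params.first_age_sd), *params.first_age_range)
        )
        ages = [age]
        for k in range(n_visits - 1):
            gap = max(params.min_gap, rng.normal(params.gap_means[k], params.gap_sds[k]))
            ages.append(ages[-1] + gap)
        u = rng.normal(0.0, params.sigma_u) if params.sigma_u > 0 else 0.0
        visits = []
        for a in ages:
            age_c = a - params.mean_age
            cag_c = cag - params.mean_cag
            eps = rng.normal(0.0, params.sigma_e) if params.sigma_e > 0 else 0.0
            log_ei = b0 + b_age * age_c + b_cag * cag_c + b_int * age_c * cag_c + b_sex * male + u + eps
            visits.append(VisitRecord(age=a, ei=float(np.exp(log_ei))))
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                cag_ref=cag,
                sex=MALE if male else FEMALE,
                visits=visits,
            )
        )
    return subjects
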