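# Methods

## The assay and its signal model

Repeat-spanning PCR across the *HTT* CAG tract, sized on a capillary
sequencer, produces one called peak per distinct repeat length present in the
template pool. For an expanded-allele carrier the profile contains a
normal-allele cluster, a dominant peak at the inherited (reference) expanded
repeat, and minor flanking peaks at 3-bp spacing. Two asymmetries make the
right-hand flank informative and the left-hand flank not: polymerase slippage
during PCR (stutter) generates products *shorter* than the template, so peaks
left of the main peak mix artifact with any somatic contractions and cannot
be deconvolved; products *longer* than the main peak can only come from
somatically expanded template molecules. Peak *heights* (not areas) are used
to weight molecule abundance; PCR is biased toward shorter alleles, so the
index understates true mosaicism — a known, uncorrected property of the
assay shared by all studies using it.

## Expansion index

After calibrating peak sizes to repeat lengths, the main peak is the tallest
on-ladder peak with repeat length ≥ `min_expanded_repeat` (default 36 — the
smallest fully penetrant HD allele class; normal alleles top out near 35).
Ties break toward the larger repeat; the tie never arises in real profiles
but the rule must be deterministic. For each right-hand peak at offset *i*
CAG units, the height ratio rᵢ = hᵢ/h_main is computed; ratios below the
relative threshold (default 0.03) are discarded — the boundary is inclusive,
i.e. exactly-3% peaks are retained, because the exclusion rule drops peaks
*below* 3% — and

EI = Σ rᵢ · i over retained offsets.

EI = 0 therefore means no detectable mosaicism. EI is invariant to uniform
rescaling of heights (ratio form), to sub-threshold peaks, to off-ladder
noise peaks, and to anything left of the main peak.

Calibration: each peak is snapped to the nearest rung of the 3-bp ladder
anchored at a known (CAG, size) pair — in production the per-plate internal
standard, in simulations the generator's main peak. Peaks deviating more
than `off_ladder_tolerance_bp` (default 1.0 bp) from their rung are flagged
off-ladder and excluded from all downstream arithmetic; off-ladder filtering
precedes the 3% threshold. The main peak is re-identified per trace, never
assumed constant across a subject's visits (the inherited-allele call can
shift by one repeat between samplings).

The mutant-allele distribution reports, over the main peak (offset 0) plus
retained right-hand peaks, each peak's height share as a percentage; shares
sum to 100 by construction.

## Per-subject trajectories

Each subject's EI is regressed on age at sampling by ordinary least squares
over all of their 2–3 visits (with two visits this is the two-point slope).
The slope is the expansion rate (ER, EI units/year); the intercept is a
theoretical EI at birth; the fitted line evaluated at the age at onset gives
the extrapolated expansion index at onset (EI-AO), including backward
extrapolation when onset precedes the first sampling. Fewer than two
distinct sampling ages leaves the slope undefined: the fit is flagged
invalid rather than raising, since repeat sampling at one age is a real
data pattern (one cohort subject). Consecutive-pair rates (ΔEI/Δage) are
computed separately for descriptive summaries only; the ER is always the
all-visits OLS slope.

**Age at onset.** Clinically, onset is recorded as the *earliest* of the
self-reported age of motor symptoms and the first neurological examination
at which the subject was manifest. The package therefore uses an effective
onset age: min(recorded onset, age of the subject's first manifest-status
visit). Four cohort subjects were observed manifest at a visit predating
their self-reported onset; only with this definition do the cohort's
extrapolated onset indices, the onset-group labels, and every onset
regression reproduce the source table to printed precision. One fixture
cell (subject 3, first visit) is printed "manifest" with a motor score of 0
and onset four years later; the table's own status counts (19 manifest / 31
premanifest at the first visit) identify this as a typo, and the loader
applies the documented correction to premanifest. The raw fixture file
stores the cell as printed.

## Cohort associations

Ages at onset and death enter regressions on the natural-log scale (to meet
normality/homoscedasticity of residuals); standalone Pearson correlations
against AO/AD are reported on the raw scale — both conventions are exact
reproductions of the source analyses, confirmed numerically. Simple
regression reports slope, intercept, Pearson r between the actually
regressed variables, the two-sided slope p from the t distribution with
n − 2 df, and adjusted R² = 1 − (1 − r²)(n − 1)/(n − 2). Missing values are
handled by pairwise deletion and the reported n is always the number of
complete pairs.

Onset groups come from the residuals of ln(AO) on reference CAG,
standardized by their sample standard deviation (n − 1 denominator) to mean
zero and unit variance: residual < −0.5 → earlier-than-expected onset,
> 0.5 → later, otherwise as expected.

Two-group comparisons use the Wilcoxon rank-sum test (asymptotic normal
approximation with mid-rank tie correction and continuity correction, via
the Mann-Whitney U formulation); three or more groups use Kruskal-Wallis.
Exact small-sample p-values are out of scope. The fully tied degenerate case
returns p = 1 instead of dividing by a zero tie-corrected variance. No
multiple-testing correction is applied anywhere, matching the source
analyses.

## Mixed model

Within-subject correlation across visits is handled by a random-intercept
linear mixed model fitted by REML (statsmodels `MixedLM`):

ln EI = β₀ + β_age·age_c + β_cag·cag_c + β_int·age_c·cag_c [+ β_sex·male]
        + u_subject + ε

Age and CAG are mean-centered at the observation level by default, so
exp(β₀) is the predicted EI for a carrier with the cohort's average age and
repeat length. Because of the interaction term the main-effect coefficients
are centering-specific; `fit_lmm` accepts explicit centering constants,
which simulation-recovery checks must pass to compare against generating
values. The sex term (male indicator, female reference) is included exactly
when per-subject sex is known — the packaged longitudinal table does not
record it, so the fixture fit is sex-free; the published sex coefficient is
small and non-significant, which bounds the resulting coefficient drift
well inside the documented tolerances.

Reported: fixed-effect estimates, standard errors, t = estimate/SE, and
p-values from a t reference with residual df (n_obs − p). The estimates,
SEs and t-values do not depend on the df convention; a Satterthwaite
approximation is not available in the backend and the df choice is
documented rather than silently approximated. Variance components are
reported as SDs; a random-intercept variance estimated at ≤ 1e-8 × residual
variance sets a `boundary` flag instead of raising. Optimizer warnings are
carried in the fit's `message`; there is no silent ML/REML fallback.

Predicted trajectories exponentiate the fixed-effects surface (random
intercept at zero) over, per CAG length, the age interval actually observed
in the cohort for that CAG, so curves never extrapolate outside the data
support; requesting an unobserved CAG warns and skips.

## Synthetic data

**Traces.** The generator emulates the anatomy the pipeline must be robust
to: a normal-allele cluster (taller than the expanded main peak, reflecting
amplification bias toward the short allele), left-hand stutter ladders for
both alleles, right-hand expansion peaks with geometrically decaying height
ratios rᵢ = a·λ^(i−1), sub-threshold tail peaks, Gaussian size jitter, and
Poisson-count spurious peaks placed 1.2–1.8 bp off the ladder. Geometric
decay is the simplest shape reproducing the qualitative profile (mass
concentrated at the main peak); it is not claimed to be the mutational
truth, and the stutter shape is irrelevant to correctness since the pipeline
must ignore it. The expected EI is available in closed form from the
parameters, making the generator an oracle for the full pipeline. Jitter is
truncated at 2.5 SD — capillary sizing error is bounded in practice — so a
jitter SD ≤ 0.4 bp can never push a peak off the 1.0 bp rung tolerance, and
generator and pipeline then agree exactly. A scale a > 1 (first expansion
peak taller than the main peak) is rejected as a parameter error. What the
generator does **not** emulate: raw fluorescence baselines, dye pull-up,
size-standard failures, somatic contractions, and amplification-bias decay
across the expansion ladder — so passing tests certify the arithmetic and
robustness of the pipeline, not assay chemistry.

**Cohorts.** Subjects draw a reference CAG (39–54, frequencies matching the
longitudinal cohort), sex (38% male), a first sampling age of 37.8 ± 12.6
years clipped to 20–76, and inter-visit gaps of 12 ± 4.9 then 6.2 ± 5.2
years (a quarter of subjects get a third visit); log-EI then follows the
random-intercept model *exactly*, with default coefficients equal to the
fitted blood-cohort model (intercept −0.603, age 0.028, CAG 0.276,
interaction 0.002, male 0.028; σ_u = 0.258, σ_e = 0.095, centered at 44.6 y
/ 44.7 CAG). Gaps are clipped at ≥ 1 year, so the generator never produces
the degenerate repeated-age pattern — that case is covered by the fixture.
Both generators are deterministic given a seed and use a private stream.

## Numerical and testing choices

- Fixture files are dot-decimal CSV mirroring the printed tables
  column-for-column; "NA" encodes missing. Printed rate/onset-index columns
  are kept as strings so tests can compare at printed precision (rate
  ±5e-5, onset index ±5e-4, allowing terminal-digit rounding).
- Problem sizes for the simulation checks: generator/pipeline consistency
  over 1000 random parameter draws; mixed-model coefficient recovery over
  500 cohorts of 200 subjects × 3 visits (enough groups for REML variance
  components, and hence fixed-effect SEs, to be well estimated — with 50
  groups the SEs ignore variance-component uncertainty and 2-SE coverage
  dips to ~93–94%); estimator bias over 500 cohorts of the 50-subject study
  design (measured bias ≤ 0.2% for the age and CAG coefficients); rank-test
  size over 10,000 null draws of 20 + 20.
- Known limitations: contractions are indistinguishable from stutter and not
  quantified; extreme mosaicism without a callable main peak (juvenile-onset
  profiles) is surfaced as a "no expanded allele / ambiguous main" error
  rather than special-cased; the EI-AO is an extrapolation, not a
  measurement, and inherits the linearity assumption of the per-subject
  fits.
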