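# cagmosaic

Quantification and longitudinal modelling of **somatic CAG-repeat mosaicism**
in Huntington disease (HD) from capillary-electrophoresis fragment analysis.

In HD, the inherited CAG repeat in *HTT* keeps expanding somatically over a
carrier's lifetime. Repeat-spanning PCR of a blood or brain DNA sample yields
a dominant "main" peak at the inherited repeat length flanked by a 3-bp ladder
of minor peaks: peaks left of the main peak are PCR stutter, while peaks to
the right can only come from somatically expanded molecules. `cagmosaic`
turns GeneMapper-style exported peak tables into an **expansion index**

```
EI = Σᵢ (hᵢ / h_main) · i        over right-hand peaks at offset i CAG units,
                                  keeping peaks with hᵢ/h_main ≥ 0.03
```

and builds the downstream inference chain used to study how mosaicism evolves
with age:

- **Expansion rate (ER)** — per-subject OLS slope of EI on age at sampling;
  the intercept is a theoretical EI at birth, and the fitted line evaluated at
  the age at motor onset gives the extrapolated **EI-AO**.
- **Onset classification** — standardized residuals of ln(AO) on the
  reference CAG length split carriers into earlier-than-expected (< −0.5),
  as-expected, and later-than-expected (> 0.5) onset groups.
- **Random-intercept mixed model** (REML) —
  `ln EI ~ age_c + cag_c + age_c:cag_c (+ sex) + (1 | subject)` with age and
  CAG mean-centered, plus back-transformed predicted EI-vs-age trajectories
  per CAG length.
- **Synthetic data** — a trace generator with closed-form ground-truth EI
  (stutter, sub-threshold peaks, size jitter, off-ladder noise) and a cohort
  generator drawing exactly from the random-intercept log-linear model, so
  every stage is testable without external data.

Three cohort tables ship as plain-text fixtures: a 50-subject longitudinal
blood cohort (112 visits over up to ~20 years), 7 fetal mutation carriers
(cortex, trophoblast, parental blood), and 15 adult post-mortem cortices.

## Worked example

```python
from cagmosaic import (
    load_cohort_fixture, cohort_trajectories, trajectory_summary,
    classify_onset, simple_regression, fit_lmm, long_format, predict_ei,
)

subjects = load_cohort_fixture("longitudinal")
fits = cohort_trajectories(subjects)
summary = trajectory_summary(fits)
print(f"valid trajectories: {summary['n_valid']}/50")
print(f"expansion rate:     {summary['er']['mean']:.4f} +/- {summary['er']['sd']:.4f} EI/yr")
print(f"EI at onset:        {summary['ei_ao']['mean']:.3f} +/- {summary['ei_ao']['sd']:.3f}")

cag = [s.cag_ref for s in subjects]
ei1 = [s.visits[0].ei for s in subjects]
res = simple_regression(ei1, cag)
print(f"EI~CAG at visit 1:  r = {res.r:.3f}, slope = {res.slope:.3f}, p = {res.p_slope:.1e}")

groups = classify_onset(subjects)
counts = {g: sum(c.group == g for c in groups) for g in ("earlier", "as_expected", "later")}
print(f"onset groups:       {counts}")

fit = fit_lmm(long_format(subjects))
age, cagc = fit.fixed_effects["age"], fit.fixed_effects["cag"]
print(f"LMM (REML, {fit.n_obs} obs / {fit.n_groups} subjects):")
print(f"  age    {age.estimate:.3f} (SE {age.se:.3f}, t = {age.t_value:.1f})")
print(f"  cag    {cagc.estimate:.3f} (SE {cagc.se:.3f}, t = {cagc.t_value:.1f})")
print(f"  predicted EI at cohort mean (44.6 y, 44.7 CAG): {predict_ei(fit, fit.mean_age, fit.mean_cag):.3f}")
```

prints

```
valid trajectories: 49/50
expansion rate:     0.0236 +/- 0.0332 EI/yr
EI at onset:        0.625 +/- 0.649
EI~CAG at visit 1:  r = 0.816, slope = 0.155, p = 5.0e-13
onset groups:       {'earlier': 14, 'as_expected': 24, 'later': 12}
LMM (REML, 112 obs / 50 subjects):
  age    0.028 (SE 0.001, t = 22.8)
  cag    0.276 (SE 0.011, t = 24.2)
  predicted EI at cohort mean (44.6 y, 44.7 CAG): 0.555
```

One subject's trajectory is degenerate (two samples at a single age: no
defined rate), hence 49 valid fits. Somatic expansion in blood grows by
~0.024 EI units per year on average, is driven most strongly by the inherited
repeat length (t = 24.2), then by age (t = 22.8), and a carrier with the
cohort's average age and repeat length has a predicted EI of ~0.55.

A `cagmosaic` command-line tool wraps the same pipeline
(`cagmosaic ei | cohort | classify | lmm | simulate`); every run echoes its
resolved configuration to a `.config.json` sidecar for reproducibility.

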