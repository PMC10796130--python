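# Methods

## Model

Time `t` is years since the index ischemic stroke. Each subject is
followed to their first recurrence (event) or end of follow-up
(right-censored); exactly one row per subject, exact event times, no
interval censoring, no competing risks, no repeated events.

The instantaneous hazard of recurrence is

    h(t | x) = h0(t) · exp( β(t)·g(t) + Σ_c β_c x_c )

with `g(t) = t` (Gompertz), `g(t) = ln t` (Weibull) or no time term
(constant hazard). `h0(t)` and `β(t)` are piecewise constant over
half-open segments `[start, next_start)`; the default structure has a
baseline break at 0.5 years (θ₁ before, θ₃ after) and a shape break at
3 years (θ₂ before, θ₄ after). Breakpoints are data stored in the model
object, not constants; they are held fixed during estimation. The hazard
is allowed to be discontinuous at breaks — no continuity constraint is
imposed, so the late-time shape θ₄ > 0 describes a mild exponential
rise after the downward jump at 3 years; the literal piecewise form is
what is implemented. At exactly `t = 0.5` the second baseline applies
and at `t = 3` the second shape (half-open segments).

Covariates are binary 0/1 baseline flags only (presence/absence of a
risk factor or a treatment at the index stroke); continuous values are
rejected. A covariate acts as a pure proportional factor `e^{β_c}` on
the hazard at every time — the hazard ratio. Profiles are strict: a
covariate the model expects must be supplied explicitly (missing ≠ 0),
and unknown names are errors.

Cumulative hazard is evaluated in exact closed form segment by segment
(`h0/β·(e^{βb}−e^{βa})` for a Gompertz piece, `h0·(b−a)` for constant or
zero shape, `h0/(β+1)·(b^{β+1}−a^{β+1})` for Weibull with shape > −1;
shapes ≤ −1 are rejected as divergent at the origin), and
`S(t) = exp(−H(t))`. Event-time simulation inverts `H(t) = −ln u`
segment by segment with the same closed forms, then applies the
subject's censoring time.

## Likelihood and estimation

OFV = −2 Σᵢ [ dᵢ ln h(tᵢ|xᵢ) − H(tᵢ|xᵢ) ]. This is a plain fixed-effect
time-to-event likelihood: no inter-individual random effects or frailty
terms are included anywhere. Ties in event times need no correction
under the exact-time likelihood.

Minimization uses L-BFGS-B with baseline rates log-parameterized
(positivity by construction) and shapes/coefficients unconstrained.
Starting values: crude event rate (events per person-year) for every
baseline segment, zero for shapes and coefficients; the stepwise search
instead warm-starts each nested refit from the current model's estimates
(`start="template"`), which also guarantees nesting monotonicity of the
OFV up to optimizer tolerance. Convergence tolerance is ~1e−8 on the
OFV; on failure the start point is jittered (N(0, 0.5) on the internal
scale) up to 20 times with a fixed-seed generator, so fits are
deterministic given data, template and settings. Non-convergence is
reported in the result, never silent.

## SIR uncertainty

RSE% and CIs come from sampling importance resampling: a multivariate
normal proposal centred at the MLE with covariance = inflation × the
inverse Hessian of OFV/2, defaults n_proposal=2000, n_resample=1000,
inflation=1.5, one iteration (all configurable). The Hessian is computed
by central finite differences on the internal scale (log baseline rates,
where curvature is well scaled) and mapped to the natural scale by the
delta method; proposals with non-positive rates or divergent Weibull
shapes get zero weight; weights are `exp(−ΔOFV/2)/q(θ)`; resampling is
without replacement (with replacement, flagged, only if fewer positive
weights than requested). A singular Hessian triggers a flagged fallback
to asymptotic standard errors. RSE% = sd(resampled)/|estimate|·100; CIs
are 2.5/97.5 percentiles.

Hazard-ratio CIs follow the convention `exp(β ∓ 1.96·(RSE/100)·|β|)`,
which is internally consistent with published tables of this analysis
type. Half-life of a Gompertz shape is `ln 2 / β`, reported at full
precision: `ln 2 / 0.242 = 2.864` (tables sometimes print 2.85 — a
rounding discrepancy of the source, documented, not reproduced).

## Stepwise covariate search

Forward: each round fits every remaining candidate on top of the current
model and includes the one with the largest OFV drop if it is ≥ 3.84
(χ²(1), p<0.05, one df per binary covariate); ties break on covariate
name for deterministic runs. Backward: repeatedly removes the covariate
whose deletion raises the OFV least, until every remaining one costs
≥ 6.64 (p<0.01). Candidate evaluation order is exhaustive-greedy each
round (the order covariates are tried does not affect the result); a
constant column is flagged uninformative (ΔOFV = 0) rather than fitted.
Thresholds are configurable flags.

## Kaplan-Meier VPC

`km_estimate` wraps the lifelines product-limit estimator (events
processed before censorings at tied times). A VPC simulates
`n_replicates` (default 1000) datasets from the model, keeping each
subject's covariates and censoring time and redrawing only the event
time, computes each replicate's KM curve on a grid — observed event
times plus 75 evenly spaced points up to 7.37 years — and reports
pointwise 2.5/50/97.5 percentile bands plus the fraction of grid points
where the observed curve lies inside the band. Bands are pointwise, not
simultaneous. Replicate `r` uses the deterministic substream
`SeedSequence(seed, spawn_key=(r,))`. The censoring time of a subject
whose event was observed is unknown; replicates use the maximum observed
follow-up for those subjects (the observed time for censored subjects),
standard KM-VPC practice; callers that know the administrative censoring
design can pass `censor_times` explicitly. The replicate loop uses a
vectorized numpy product-limit routine that is cross-checked against
lifelines in the tests.

## Synthetic cohorts

The generator emulates the registry cohorts the analysis assumes:
covariates drawn independently as Bernoulli with the published
prevalences (the true joint distribution is unknown — independence is a
documented simplification, so e.g. the real IHD/HPLD correlation and any
covariate-censoring dependence are not reproduced); censoring either
fixed at the 7.37-year maximum follow-up or uniform over an accrual
window, default U(0.37, 7.37) years, mimicking staggered registration
against a fixed cutoff (the real per-subject follow-up distribution is
unpublished); event times by inverse-CDF sampling from the generative
truth. Presets `dm_base`/`dm_final` (n=3493) and `nondm_base`/
`nondm_final` (n=4204) carry the published parameters as truth.
Consequently, passing tests demonstrate correct self-consistent
recovery, calibration and validation behaviour under the assumed model —
not goodness of fit to the real registry, whose event fractions depend
on the unpublished follow-up distribution. Age, ethnicity, smoking
duration, stroke-severity scores and other descriptive fields are not
generated; only covariates entering the final models plus optional
decoy flags (smoking, atrial fibrillation, hyperuricemia, family
history, lipid-lowering therapy) for selection studies.

## Risk calculator

Cumulative recurrence risk by `t` is `1 − S(t)`; the windowed variant
`1 − S(t₂)/S(t₁)` is the risk within `(t₁, t₂]` conditional on no
recurrence by `t₁`. Both are exposed because "risk after t years" is
ambiguous in clinical use; the cumulative form is monotone in `t` and in
any risk factor with positive coefficient. Hosted web calculators built
on models of this family do not document their formula; this package
only reports the two transparent quantities above.

## Numerical choices and problem sizes

- Closed-form cumulative hazards agree with adaptive quadrature to
  ≤ 1e−8 relative error (property-tested over random models of all
  three families).
- LRT tolerance: an OFV increase up to 1e−4 after adding a parameter is
  treated as optimizer noise (clamped to zero), larger negative drops
  are errors.
- Finite-difference Hessian steps: 1e−3 × max(|x|, 0.1) per internal
  coordinate.
- Test-suite problem sizes mirror the study where the check depends on
  them (n=3493 development and n=1262 temporal-validation cohorts, 1000
  VPC replicates, 20 stepwise replicates); smaller cohorts (a few
  hundred to a few thousand subjects) are used for unit-level
  distributional checks where the property is size-insensitive.

## Known limitations

- No frailty/random effects, time-varying covariates, interval or left
  censoring, competing risks, or recurrent-event modelling.
- Covariate independence in the generator (above).
- Percentile VPC bands are not prediction-corrected and carry the usual
  pointwise-coverage caveat.
- Breakpoints are fixed, not estimated; model comparison across
  breakpoint choices is left to the user via OFV.
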