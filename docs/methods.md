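# Methods

## Structural and statistical model

One-compartment disposition with first-order elimination and zero-order
(constant-rate) infusion input. All units are fixed: dose mg, volume L,
time h, concentration µg/mL (≡ mg/L); no unit inference. Bolus dosing is
deliberately unsupported — every regimen of interest is an infusion, and
excluding `Tinf = 0` removes a discontinuous special case.

Between-subject variability is lognormal on clearance and volume with a
full 2×2 covariance (volume first): `CL_i = TVCL·exp(η_CL)`,
`V_i = TVV·exp(η_V)`, `(η_V, η_CL) ~ N(0, Ω)`. Residual error is
proportional: `y = f·(1+ε)`, `ε ~ N(0, σ²)`. Observed-data predictions are
computed by superposition over each subject's recorded dose events; the
infusion-profile kernels are precomputed per dataset, and the same
prediction function serves estimation, simulation and the synthetic
generator, so a noise-free cohort is recovered exactly by the fit.
Steady-state quantities used by the Monte Carlo engine (peak, trough,
%fT>MIC, AUC24 = daily dose / CL) use the closed-form geometric
accumulation instead; finite superposition is retained as a test oracle
(they agree to <1e-9 relative at 200 doses).

%fT>MIC is evaluated on one steady-state dosing interval `[0, τ)` with the
trough at the interval end. The free profile rises monotonically from the
trough during the infusion and decays monotonically after the peak, so
there are at most two MIC crossings, solved in closed form; a dense-grid
evaluation (step τ/1e5) agrees within 0.05 percentage points across
randomised sweeps.

## Published parameter values and their ambiguities

Defaults (`table3_estimates()`): TVCL 5.9 L/h, TVV 41.1 L, IIV 24.8% (CL)
and 36.3% (V), η covariance −0.0901, proportional residual error 0.114.
Three reporting ambiguities are handled explicitly:

- **σ scale.** 0.114 is read as the proportional-error *standard deviation*
  (≈11.4% CV), consistent with the tight goodness of fit described;
  `sigma_interpretation="variance"` selects √0.114 instead.
- **IIV scale.** The percentages are read as 100·ω (log-scale SDs);
  `iiv_interpretation="exact_cv"` solves CV% = 100·√(exp(ω²)−1) instead.
- **Ω positive-definiteness.** The printed triple implies a correlation of
  −1.0009, which is impossible and presumably rounding. The default repair
  clips the correlation to −0.999 and recomputes the covariance, preserving
  the printed variances. The repair is explicit
  (`PopEstimates.repaired()`), reported by the pipeline log whenever
  applied, and required before sampling or likelihood evaluation.

## Estimation

The marginal likelihood integrates η per subject with the Laplace
approximation at the posterior mode; −2·log L is the objective (OFV),
additive over subjects. Adaptive Gauss–Hermite quadrature
(`eta_method="adaptive-quadrature"`) is available as a higher-accuracy
alternative and as a cross-check; on model-consistent toy datasets with
σ = 0.08 the Laplace error is below 0.05 OFV units, and it grows roughly
linearly in the subject count and in σ (≈0.05/subject at σ ≈ 0.12 for
3-sample subjects) — a known property of the approximation under
proportional error, not an implementation artefact (the built-in quadrature
matches an independent oracle to 1e-6).

Numerical choices that turned out to matter:

- **Inner problem.** On sparse designs (six samples in one interval) the
  per-subject η posterior can be *multimodal* — a clearance/volume
  trade-off. The mode is therefore located by scanning a 9×9 grid scaled by
  the prior covariance (±3 SD) and refining the best point with a damped
  exact-Hessian Newton iteration. Taking the per-subject global mode makes
  the Laplace objective a minimum of smooth surfaces — continuous in the
  population parameters — where naive mode-tracking would jump between
  basins and corrupt finite-difference gradients.
- **Derivatives.** Inner gradients use complex-step differentiation
  (exact to machine precision); the Laplace curvature is a central finite
  difference of that gradient. The outer gradient is a forward difference
  (step 1e-5), with the base point and all perturbed replicas solved in a
  single stacked inner problem.
- **Inner convergence.** The Newton iteration stops when the Newton
  decrement (the expected remaining decrease of the penalised objective)
  falls below 1e-8. An absolute gradient tolerance is unattainable when the
  outer optimiser explores very small ω (prior curvature ~1/ω²).
- **Outer optimisation.** L-BFGS-B on an unconstrained scale: logs of the
  typical values and ω/σ, correlation through arctanh, so Ω remains valid
  throughout. ω and σ are bounded in [e⁻⁷, e²] — values outside that range
  only arise as degenerate attractors. Multi-start (default 5): the
  supplied init, a crude data-driven init (clearance from the mean
  steady-state concentration, volume from the peak–trough swing), and
  jittered variants; the best optimum is returned. Stopping tolerances sit
  just above the inner-solve noise floor (~1e-6 OFV); tighter settings only
  polish noise.
- **Degenerate inputs.** Subjects with no retained observations contribute
  exactly 0 to the OFV and receive population typical values as EBEs (with
  a complete-shrinkage warning). Below-LLOQ (or above-ULOQ) observations
  are dropped with a count warning — the source study excluded the affected
  patients entirely; censored-likelihood (M3) handling is out of scope.
  With fewer subjects than random effects the η correlation is fixed to 0.

Covariate search is stepwise: power models `θ·(cov/median)^β` for
continuous covariates, proportional shifts `θ·e^{β·x}` for binary ones;
forward inclusion needs ΔOFV ≥ 3.84 (χ², 1 df, p<0.05), backward
elimination removes anything whose removal costs < 6.63 (p>0.01); every
tested ΔOFV is returned in a ledger. Constant covariates are skipped with a
warning.

The nonparametric bootstrap resamples subjects with replacement (same count
per replicate), refits each replicate from the original point estimate with
a single start, and reports 2.5/50/97.5 percentiles of the converged
replicates; non-converged replicates are counted and excluded, with a
warning above 20%. The VPC simulates each subject's own design (dose
schedule, sampling times, residual error included) and reports observed
5/50/95th percentiles per nominal timepoint with 95% simulation intervals;
timepoints with fewer than three observations are suppressed.

## Synthetic cohorts

`generate_cohort` reproduces the study design: 9 subjects on 600 mg/0.5 h
infusions q8h, six doses before the sampled interval, samples pre-dose
(offset 0 = trough of the preceding interval; the source's exact
dose-to-sample alignment is not stated) and at 0.5, 1, 2, 4, 6 h after the
infusion start, with the 8th subject's 0.5 h sample missing — 53
observations from 9 subjects. Truth defaults to the published estimates.
Proportional noise is truncated at −0.999 on the relative scale so
concentrations stay positive; values outside the 0.75–30 µg/mL assay range
are flagged, not clamped. `sigma_prop = 0` is accepted for simulation (the
deterministic limit) though estimation requires σ > 0.

What the generator does *not* emulate: covariate-driven parameter
heterogeneity (available through `TruthSpec`, off by default), ECMO-circuit
drug sequestration, time-varying clearance (e.g. dialysis), inter-occasion
variability, and assay bias. Passing tests therefore demonstrate that the
estimator and simulator are correct *under the stated model*, not that the
model captures every feature of real ECMO patients.

The bundled MIC frequency tables are synthetic toys (so named in their
files and labels) chosen to span susceptible-to-resistant profiles on the
default two-fold grid; real CFR analyses must load surveillance data.

## Monte Carlo PTA / CFR

5000 patients are sampled per evaluation (`(η_V, η_CL)` from the repaired
Ω). Attainment uses residual-error-free ("true") concentrations: PK/PD
attainment concerns the patient's exposure, not assay noise — the
convention is confirmed by the closed-form cross-check below. fAUC targets
use the steady-state identity `fAUC24 = fub·daily_dose/CL`, so their PTA
has an exact lognormal form, `PTA = Φ(ln(fub·D_daily/(thr·MIC·TVCL))/ω_CL)`,
used as an oracle in the tests (at q8h, MIC 2, threshold 80 it gives 86.6%,
matching the published 87.44% within Monte Carlo and rounding error).
Attainment comparisons use ≥ (configurable to strict >). The default MIC
grid is the two-fold series 0.0625–16 mg/L; CFR requires every distribution
MIC to be on the grid exactly — no silent interpolation. The 90% PTA and
90% CFR conventions are reported alongside the curves.

Trough safety counts use the conventional 2–8 mg/L window (inclusive at
both ends) and a strict `> 8 mg/L` toxicity flag. On the nine published
individual troughs this gives 5 above the threshold, 3 in the window and 1
below — the source text's prose says "four" in-window, which its own table
and its own "all but one above 2 µg/mL" statement contradict; the package
reports what the data give.

## Test and simulation sizes

Replicate counts in the test suite are scaled to desk hardware as the
package's own defaults: parameter-recovery bias uses 200 replicates of the
9-subject design; bootstrap coverage uses 16 study replicates at B = 60
(the pipeline default is B = 200, and B = 1000 — as in the source analysis —
remains a config choice); VPC self-consistency uses 400 replicates;
covariate retention checks use single cohorts of 20–40 subjects. The
Laplace-vs-quadrature comparison uses two 3-sample subjects at σ = 0.08,
where the approximation is in its accurate regime (see above for how the
gap scales).

## Known limitations

- Laplace (not FOCE-I) is the estimation objective; no attempt is made to
  match a specific NONMEM method flag. CWRES are not computed; standard
  residuals against individual/population predictions are available from
  the EBE and VPC tables.
- Percentile bootstrap on 9 subjects is honest but crude; intervals at
  small B are noisy, and coverage slightly below nominal is expected.
- Proportional error means the EBE mode never fully decouples from the data
  as σ grows (the log-variance term retains η), and σ = 0 is usable only
  for simulation.
- Two-compartment or nonlinear elimination, oral absorption, censored-
  likelihood BLLOQ handling, and toxicodynamic modelling of
  thrombocytopenia are out of scope.
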