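# Methods

This note documents the models implemented in `sglt2mbma`, the estimation
machinery, the synthetic-data generator that stands in for literature-digitized
meta-data, and the numerical and design choices that were genuinely open.

## Scope and data model

The package works entirely on **summary-level (arm-mean) data**: each record
is the mean of one treatment arm of one study at one time point, together
with the arm size `n`.  Three tidy CSV schemas carry the pipeline —
concentration–time records, 24-h urinary glucose excretion (UGE) records
with baselines, and FPG/HbA1c time courses with baselines — mirroring what
can be extracted from published trial reports.  No subject-level data exist
anywhere in the pipeline, which is why inter-study (not inter-individual)
random effects are the relevant variability level.

## PK model

Disposition is a linear two-compartment model (apparent parameters CL, Vc,
CLD, VT; bioavailability absorbed into them since all source data are oral).
Absorption is a transit chain: depot → n identical transit compartments →
central, every transfer governed by the single rate constant Kt.  The chain
topology is a modelling choice — one shared rate is the most parsimonious
structure consistent with a single estimated Kt per drug — and n is fixed
per drug (2 for dapagliflozin and empagliflozin, 4 for canagliflozin), not
estimated.  The fed state multiplies Kt by a factor (0.254 for
dapagliflozin), slowing absorption; the multiplicative form is chosen over
a (1 + effect) proportional-change form because the factor is estimated
below 1 and food delays, not abolishes, absorption.

Because the system is linear and non-stiff, the default solver is the exact
matrix-exponential propagator over the merged sequence of dose events and
observation times (dose = impulse into the depot; the propagator for each
distinct step length is computed once and cached).  A general-purpose
`solve_ivp` integration of the same system, augmented with a cumulative
elimination state, serves as the independent cross-check oracle: the test
suite requires agreement to < 1e-6 relative and mass balance
(depot + chain + central + peripheral + eliminated = administered dose) to
1e-6 relative.  Steady-state 24-h exposure uses the analytic identity
AUC_ss,τ = dose/CL (scaled by 24/τ for non-daily intervals); numeric
quadrature of simulated profiles reproduces it to < 1e-3.

Units: hours, mg, L, L/h; concentrations in ng/mL (mg/L × 1000).

## Biomarker model

ΔUGEc = (UGE − UGE_baseline)/FPG_baseline, in g/(mg/dL).  The published
equation typesets ambiguously; the implementation follows the verbal
definition ("change of UGE from baseline corrected by baseline FPG"), i.e.
the difference is taken before dividing.  Exposure–response is
ΔUGEc = Emax·AUC/(EC50 + AUC) with a class-shared Emax and per-drug EC50,
evaluated at steady-state exposure only — one ΔUGEc per arm, no within-day
UGE kinetics.  Healthy and T2DM arms share the curve; the population label
is carried only for stratified diagnostics.

A stand-alone mechanistic rate,
dUGE/dt = GFR·PG − f_reabs·GFR·PG·(1 − Imax·C/(IC50 + C)), documents why the
FPG normalization works (excretion is filtration minus inhibitable
reabsorption, and filtration scales with plasma glucose).  The operation
harmonizes GFR (mL/min) and PG (mg/dL) to g/h via the factor
60/(100·1000); it is a consistency check, never integrated over time.

EC50 and AUC units are ng/mL·h throughout.

## Endpoint models

Time unit: weeks.  Progression rates are stored per 100 weeks as published
and divided by 100 at evaluation.

**FPG** (algebraic):
`FPG(t) = B + P_fmax[g]·(1 − e^(−K_fp·t)) + (DIS_fp/100)·t + SLOPE_fd·ΔUGEc`,
with the placebo maximum stratified by treatment type g (naive, non-naive,
add-on, mixed — add-on arms have a negative placebo maximum because the
background therapy keeps improving glycemia).  All placebo-maximum
parameters are signed and enter additively; the same convention is used for
HbA1c, where the published estimates are negative for decreases.  The drug
effect is a step from t = 0: steady-state exposure is reached within the
first endpoint observation interval, so no onset ramp is modelled by
default (a ramp hook exists but is off).

**HbA1c**: an empirical placebo curve of the same exponential-plus-drift
form, plus a turnover (indirect-response) deviation H(t) with production
driven by the FPG ratio to baseline and first-order loss K_out.  The
production intercept K_in is tied to baseline, K_in = K_out·HbA1c_b − K_in2
(K_in2 is the FPG-independent input, standing for post-prandial glucose and
other contributors), which makes the untreated baseline an exact steady
state; configurations with K_in ≤ 0 are rejected as inconsistent.

Two deliberate conventions:

* The loss term acts on baseline + deviation, so H ≡ 0 whenever FPG stays
  at baseline (stationarity is exact, tested to 1e-8 over 200 weeks).
* H is forced by the **drug-attributable** FPG displacement
  (SLOPE_fd·ΔUGEc) only.  Forcing it with the total FPG (placebo included)
  would double-count placebo effects already captured by the empirical
  placebo HbA1c curve and would make a placebo arm deviate from that curve;
  with this convention a placebo arm reproduces the placebo curve exactly.

For a constant (step) displacement the deviation has the closed form
H(t) = (ΔFPG/FPG_b)·(K_in/K_out)·(1 − e^(−K_out·t)); this fast path is what
estimation and simulation evaluate, with the general `solve_ivp` route
(arbitrary FPG trajectories) kept as its oracle — the two agree to < 1e-6.

Arm-specific observed baselines drive the predictions when present; a
switch (`use_population_baseline`) substitutes the population estimates
(160 mg/dL, 7.92 %).

## Estimation

All stages share one estimator.  The residual model for an arm mean is
Var(y) = (σ²_prop·f² + σ²_add)/n — residual SD shrinking as 1/√n is the
standard-error-of-a-mean reading of "weighting data by the square root of
sample size".  Residual variances are fixed at their configured values
(defaults: the published estimates); only structural parameters are
estimated.

The default optimization is **iteratively reweighted least squares**:
weights are frozen at the variance evaluated at the current predictions,
Σ(y−f)²/V is minimized, and the weights are refreshed (3 passes).  Two
alternatives are selectable and document why the default is what it is:

* `variance_reference="prediction"` — the extended-least-squares objective
  Σ[(y−f)²/V(f) + ln V(f)].  Its ln V term rewards small predictions and
  biases even noise-free recovery measurably (~2 % on clearance in the PK
  stage), so it is not the default.
* `variance_reference="observation"` — weights from the observed values.
  Under the large proportional error of the PK stage this overweights
  low-noise-realization points and biased clearance by ~+13 % in
  calibration runs.

The GLS default is unbiased in those same calibration runs and recovers
noise-free data exactly (a test asserts < 0.1 % on every PK parameter).
The reported OFV is Σ[(y−f)²/V + ln V] at the optimum for NONMEM-style
nested-model bookkeeping (`compare_ofv` reports ΔOFV and Δ#parameters, no
automatic decision).

Optimization: positive parameters on the log scale, signed parameters
(P_fmax, P_hmax, SLOPE_fd) untransformed; 5 jittered Nelder–Mead starts
(seeded, jitter SD 0.1 on the estimation scale) with L-BFGS-B refinement of
the best.  Standard errors come from the inverse Hessian (central
differences) of the frozen-weight objective, reported as RSE%; a
non-positive-definite Hessian flags the fit (infinite RSEs, message) rather
than raising — sparse one-dose designs land there by construction.

The stages run sequentially, mirroring how the models were built: PK per
drug → shared-Emax biomarker fit (pooling all drugs; a single-drug dataset
triggers an explicit warning that the shared-Emax constraint is idle) →
endpoint placebo parameters from placebo arms → drug parameters
(SLOPE_fd, then K_out and K_in2) from drug arms conditional on the placebo
estimates.  A `joint` mode runs both endpoint blocks in one call.
Inter-study random effects are not integrated into the objective; the
`marginal_iiv` switch is a reserved hook for a first-order marginal
approximation, off by default — the recovery calibration below shows the
fixed-effect targets are met without it.

## Synthetic-data generator

The generator is the package's study-condition definition, not a test
convenience.  Defaults:

* **Truth** = the published fixed-effect estimates (Tables of the source
  model), including residual variances and inter-study variability
  magnitudes; variabilities printed as "–" default to zero (notably
  Emax/EC50), and that choice is flagged in the emitted truth file.
* **PK catalog**: 12 single-dose studies per drug, two dose levels
  (5/10 mg dapagliflozin, 100/300 mg canagliflozin, 10/25 mg
  empagliflozin), 10 sampling times over 48 h, arm sizes 12–36, fed arms
  present for dapagliflozin.
* **Biomarker catalog**: 27 arms (9 doses × 3 drugs, n = 24) spanning each
  drug's EC50 on the AUC axis, alternating healthy/T2DM populations.
* **Endpoint catalog**: 40 studies (10 per treatment type), each one
  placebo arm plus two dose arms of one drug, observations spanning 0–52
  weeks, arm sizes 50–500.  The deterministic grid-assignment rules emit
  exactly 195 placebo + 653 drug FPG points and 290 + 929 HbA1c points —
  the data volume of the source meta-analysis.

Noise structure: arm means are `f·(1 + ε_p/√n) + ε_a/√n` with
ε ~ N(0, σ²); study-level effects are additive on P_fmax/P_hmax (absolute
SDs) and exponential (log-normal multipliers) on everything else, drawn
once per study and shared by all its arms (tested: the drug-minus-placebo
FPG displacement within a study is time-constant, and realized baselines
match across arms).  Randomness is disciplined: every study derives its own
`SeedSequence([seed, stream, index])` substream, so adding a study never
perturbs existing draws, and every generator is a pure function of
(truth, designs, seed).

One reading decision: the published IIV column is headed "%", but for the
additively-varying placebo maxima an absolute SD in parameter units is the
only self-consistent interpretation (e.g. SD 5.74 mg/dL against
P_fmax = 1.45 mg/dL — placebo drift genuinely differs that much between
studies); fractional readings apply everywhere else.  Likewise the
endpoint residual variances are taken at face value as additive variances
(0.0330 mg²/dL², 0.006 %²), which makes inter-study variability the
dominant endpoint noise — consistent with arm means of hundreds of
patients.

What the generator does **not** emulate: plot-digitization error, dropout
and missingness, within-day UGE kinetics, renal-function strata, or
correlation between a study's design and its effect sizes.  Passing
recovery tests therefore demonstrate estimator correctness under the
modelled noise structure, not robustness to those real-data features.

A `generate_new_drug_scenario` rehearses the translational workflow for a
hypothetical fourth same-in-class drug: its PK parameters and EC50 are
supplied, Emax and all endpoint parameters are inherited as
system-specific.  The packaged default new-drug profile is a synthetic
stand-in (clearance loosely shaped on public fourth-in-class population-PK
reports; EC50 invented).

## Prediction and validation

**VPC**: `n_sim` (≥ 200) replicate meta-datasets are simulated under the
fitted parameters with full inter-study and residual variability and
compared per time bin and treatment-type stratum: observed 5/50/95
percentiles against the pooled simulated 5/50/95 band, plus a 95 %
Monte-Carlo envelope of the simulated median.  Bins are the exact design
times (the catalogs share grids); empty strata are skipped with a warning.
Self-simulated data cover the 5–95 band at 0.90 ± 0.05 in the test suite.

**New-drug prediction**: parameter uncertainty is propagated by a normal
approximation on the estimation scale (log-normal for positive parameters,
relative-normal for the signed slope), on top of inter-study and residual
variability; 500+ simulated trajectories yield the 90 % prediction
interval.  Both uncertainty and variability are included by default, each
switchable — with everything off the band collapses onto the deterministic
model curve (tested).  Held-out synthetic arms fall inside the 90 % band at
the expected ~0.9 rate.

**Diagnostics**: residual tables use population predictions and
√n-standardized residuals of the weighted fit.  This is a deliberate
desk-scale stand-in for conditional weighted residuals — without
conditional estimation of study-level effects, study variability appears in
the residuals, so these diagnostics are trend detectors (a halved-exposure
misspecification produces a one-sided residual pattern, tested), not
calibrated N(0,1) quantities.

## Recovery calibration and problem sizes

With the default catalogs and seeds, the estimator recovers (tests assert
these tolerances): clearance within 10 % (PK, 120 observations); the shared
Emax within 10 % and the EC50s within 25–30 % (biomarker, 27 arms); the FPG
drug-effect slope within 15 % and the progression rate within 40 %
(endpoints, 848 FPG / 1219 HbA1c points).  A 30-seed calibration shows the
estimates are unbiased with per-seed SDs of ~4 % (Emax) and ~19–26 %
(EC50s) — the same precision the source analysis reports for its own
estimates — so individual seeds scatter within those bands; the EC50
tolerances are exactly one such SD.  These problem sizes keep the whole
suite under a minute of CPU while exercising every stage at the source
data volume.

## Known limitations

* No subject-level likelihood: FOCE-style conditional estimation and
  shrinkage diagnostics are out of scope; fixed effects are the targets.
* Add-on arms confound background-therapy efficacy with placebo response;
  the model inherits that limitation from its data.
* The PK stage assumes single-dose arm profiles (the concentration schema
  carries no regimen columns); steady-state exposure always comes from the
  analytic dose/CL, so the chain loses nothing, but multi-dose
  concentration *fitting* is not implemented.
* Renal/hepatic impairment strata, insulin co-therapy, and nonlinear PK
  are excluded by construction.
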