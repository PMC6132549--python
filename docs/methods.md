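# Methods

This note documents the models and procedures implemented in `levocarb`,
their assumptions, the numerical choices behind them, and what the
synthetic-data studies can and cannot demonstrate.

## Structural model

Each drug (levodopa, carbidopa) is described by:

* **Absorption.** The dose is split between two parallel transit chains:
  fraction fa₁ into a fast chain of n₁ compartments with mean transit time
  MTT₁, and 1 − fa₁ into a slow chain (n₂, MTT₂). With the convention
  ktr = (n + 1)/MTT, the rate of drug entering the central compartment
  from one chain is the Erlang density of shape n + 1 scaled by
  F·fa·Dose. The two staggered inputs generate the double-peak profiles
  characteristic of dissolved LD/CD microtablet dosing (a phenomenon
  attributed to interrupted gastric emptying; the chains are an empirical
  description, not a mechanism). Chain lengths are fixed integers — (5, 6)
  for levodopa and (3, 10) for carbidopa in the packaged models; a grid
  search utility (`estimate.transit_grid_search`) refits over candidate
  lengths but they are never estimated inside a fit.
* **Disposition.** Two-compartment for levodopa (CL/F, V_C/F, Q/F,
  V_P/F), one-compartment for carbidopa. All parameters are apparent
  (oral) values.
* **Pre-dose baseline.** Patients with advanced disease retain measurable
  drug after an overnight washout. A pre-dose concentration C0 decays at
  the subject's terminal slope λ_z; before the first dose the same
  exponential is evaluated at the (negative) time offset, i.e. the
  baseline is back-extrapolated to the pre-dose sampling time.

### Exact profile evaluation

The system is linear and time-invariant, so the central concentration is
a finite sum of convolutions of an Erlang density with the disposition
exponentials — there is nothing to integrate numerically. The kernel
`I(τ) = ∫ Erlang(s; m, ktr)·e^{−λ(τ−s)} ds` is evaluated in three regimes
on x = (ktr − λ)τ: log-space through the regularised lower incomplete
gamma for x > 0 (machine precision, no cancellation), a globally
convergent power series for moderately negative x, and a two-term closed
form for strongly negative x. Worst-case relative error against a
high-precision quadrature oracle is ~1e-5 (attained only in the transient
λ ≫ ktr regime the optimiser may pass through); in the physiological
regime the kernel is accurate to machine precision. An LSODA integration
path (rtol 1e-8, atol 1e-10) is retained behind
`predict_concentration(..., method="ode")` and `predict_amounts` as an
independent cross-check and for mass-balance audits; the analytic path is
the production default because estimation, selection and VPC budgets
require ~10⁵–10⁶ profile evaluations per analysis.

A per-dose clearance axis is supported so that dose-specific covariate
exposure (the cumulative-carbidopa convention in external evaluation) can
be expressed without leaving the superposition framework; each dose's
response is then eliminated at the clearance in force at its intake,
which is an approximation to a truly time-varying clearance.

## Covariate model

Effects compose in a fixed order — allometry, then linear effects (they
commute), then the interaction divisor:

* allometric: θ·(WT/70)^k with k fixed at 0.75 (clearances) or 1 (volumes);
* linear: θ·(1 + β·(COV − C̄OV)), centred at pooled means that are model
  constants (age 48.7 y, sex 0.389, Hoehn & Yahr 1.53) rather than
  recomputed per dataset, so typical values reproduce the reference
  parameter table exactly;
* interaction: θ/(1 + CD/INTER), the competitive-inhibition form for the
  carbidopa dose effect on levodopa clearance (INTER = 86.7 mg).

The linear form is not sign-safe: a large |β| can drive a parameter
negative for extreme covariate values. The scalar API rejects such
configurations with an error naming the covariate; inside estimation the
objective instead returns a penalty that grows with the violation, and
covariate coefficients additionally receive per-dataset bounds
(|β| < 0.995 / max|COV − ref|) so the optimiser cannot enter the
infeasible region.

Random effects are applied after the covariate factors, each on its own
scale: multiplicative e^η (log-normal) for positive parameters, additive
on logit(fa₁) (so fa₁ stays in (0, 1)), additive for plainly normal
parameters. The reference table states only that "absorption-related"
parameters are normal; we take that to mean the logit-scale fa₁ effect and
keep log-normal IIV elsewhere, which both preserves positivity and matches
the reported CV-style magnitudes.

## Synthetic studies

`popsim` emulates three designs: a dense single-dose study in 18 healthy
volunteers (100/25 mg, 19 samples to 24 h), an individualized single-dose
study in 18 patients (110–410 mg levodopa in 5-mg steps with carbidopa at
1:4, 15 samples to 6 h, positive pre-dose concentrations), and a sparse
multiple-dose study in 10 healthy volunteers (75/18.75 mg then five
45/11.25 mg doses every 2.4 h, samples 5 min before and 20/40/60/90 min
after each dose). Demographics are truncated normals with the published
mean/SD/range; the Hoehn & Yahr stage is drawn as an integer; covariates
are sampled independently (the published table gives marginals only, so no
correlation structure is imposed). Healthy designs zero the pre-dose
baseline (washed-out cohorts).

Residual error is combined proportional+additive, with separate magnitudes
for healthy subjects and patients, and the LD/CD pair measured in the same
physical sample is drawn from a bivariate normal with correlation 0.285 —
the estimated shared fraction of the total residual error. (The
epsilon-splitting parameterisation used in the source software is
equivalent at the level of the implied joint distribution; the correlation
form is adopted for clarity.) Simulated concentrations are truncated at
zero, which slightly distorts the noise distribution only where the
signal is at the assay noise floor.

Below-limit handling is the M6 rule: within each subject-by-drug series,
every maximal run of consecutive observations below the LOD keeps only its
first record, re-assigned LOD/2 and flagged; the rest of the run is
deleted. "First value" is read per run (the standard form of the rule);
the alternative reading (first BLQ overall) is not offered. Default LODs
(0.0005 µg/mL levodopa, 0.0002 µg/mL carbidopa) were calibrated once so
that ≈5.6% of observations in a simulated pooled single-dose dataset fall
below the limit, matching the reported censoring fraction, and are stored
in the packaged design files.

Randomness follows a strict contract: one seed spawns covariate, eta and
residual substreams, each split per subject, so enlarging a cohort leaves
the earlier subjects' data bit-identical.

**What passing these simulations shows — and does not.** The generator is
the model; recovery and selection results therefore demonstrate the
correctness and statistical efficiency of the machinery under the model's
own assumptions (no model misspecification, no assay drift or plate
effects, no dropout beyond schedule truncation, no covariate correlation,
no double-peak *absence* in a subpopulation). They do not certify
performance on real clinical data.

## Estimation

The per-subject marginal likelihood is approximated by the Laplace method
with exact inner modes: for each subject the conditional eta mode is found
by a damped Newton iteration (batched across subjects; central-difference
gradient and Hessian in eta space, step 1e-4) and the mode curvature
supplies the Gaussian correction, giving OFV = −2 log L̂ including all
constants. Because the proportional residual SD is evaluated at the
individual prediction, the eta-dependence of the residual variance (the
"interaction" refinement of conditional estimation) is retained. This is
the same estimand as the reference software's conditional method but not
a replication of its linearisation; OFV values are comparable between
nested fits of this package, not across packages.

Numerical choices: the inner iteration stops when the gradient norm falls
below 1e-6 (central differences cannot certify much below that; near very
sharp proportional-error minima the curvature makes even that unreachable,
so a Newton-step-size criterion of 1e-7 and a minimum-improvement cut of
1e-9 also terminate), steps are capped at 2 eta units with backtracking,
indefinite Hessians receive a scale-aware ridge, and etas are clipped to
|η| ≤ 20. The outer problem is bounded quasi-Newton (L-BFGS-B) over
transformed parameters — log for positive quantities, logit for fa₁ and
the shared fraction, identity (with feasibility bounds) for covariate
coefficients — with forward-difference steps of 1e-5 and warm-started
inner modes across objective evaluations. Standard errors come from a
central-difference Hessian of the OFV (step 1e-4) mapped to the natural
scale by the delta method. Residual additive terms fixed at zero in a
model (levodopa in patients) must stay fixed: freeing them against data
containing exact zero-prediction/zero-observation records makes the
likelihood drift degenerately toward a zero SD.

Degenerate inputs: a residual SD floor of 1e-10 guards zero-signal
records; omega entries with zero variance simply deactivate their eta (an
all-zero omega reduces the OFV to the naively pooled Gaussian
−2 log-likelihood exactly).

Both sequential (carbidopa first, then levodopa with the carbidopa dose
as covariate — the workflow used for the reference models) and joint
estimation are provided; the joint objective models the shared-sample
residual correlation with bivariate terms at paired time points.

`lrt` converts OFV differences of nested fits to chi-square upper-tail
p-values (ΔOFV 3.84 at 1 df ⇒ p ≈ 0.05). `run_sir` draws from a
multivariate-normal proposal, weights by exp(−ΔOFV/2) over the proposal
density, and resamples without replacement (exponential-key weighted
sampling); an effective sample size below 10% of the proposal size
triggers a warning.

## Covariate selection (adjusted adaptive LASSO)

Candidate relations enter a full model as linear effects on standardised
covariates (mean 0, SD 1 across subjects, n − 1 denominator; a
standardised coefficient β on z is stored in the model as β/SD centred at
the covariate mean, so back-transformation is exact by construction).
One unpenalised fit provides ML coefficients and their standard errors
(block Hessian over the coefficients); the adaptive weight is
w = |SE/β̂|, clipped to 1e6 for near-zero β̂ — large weights price null
covariates out. The penalised fit maximises the population likelihood
subject to Σ w·|β| ≤ t, implemented by splitting each scaled coefficient
into non-negative parts so the constraint is a smooth linear inequality
(SLSQP); inactive coefficients sit exactly at zero, and the reported
solution is projected onto the constraint so it holds to machine
precision.

t is chosen by k-fold cross-validation stratified on study association;
the held-out error of a fold is its Laplace OFV under the training
estimates with only the etas re-estimated. The grid spans 0 to
1.2 × Σ w·|β̂_ML| (the point where the unconstrained optimum becomes
feasible); the minimum-error t is selected (no one-standard-error rule).
Two training modes exist: `refit_structural="always"` re-estimates every
structural parameter at every t (the default, and what the simulation
studies use), and `"first"`, which re-estimates them once per fold
(unpenalised, warm-started from the full-data fit) and then moves only
the coefficients along the t-path. `"first"` is several-fold cheaper but
anti-conservative: the frozen structural values were estimated jointly
with the unshrunk coefficients, so the held-out error of small-t models
is inflated and cross-validation leans toward inclusion. Null-covariate
simulations confirmed the effect (near-empty selections in ~65% of
replicates under `"first"` versus ~90% under `"always"`), which is why
the operating-characteristic studies pay for the faithful mode and
recover the budget through a coarse t-grid and a loose SLSQP objective
tolerance (0.01 OFV — cross-validation decisions are an order of
magnitude larger).

## Diagnostics

The VPC simulates replicates on the observed design matrix verbatim
(doses, covariates, times; fresh etas and residuals), applies the same
below-limit handling, and compares observed 10th/50th/90th percentiles per
bin against the 5th–95th band of each percentile across replicates.
Prediction correction multiplies each observation by
median(PRED in bin)/PRED with PRED the typical (eta = 0) prediction;
records with PRED = 0 and a positive observation are excluded with a
warning. Bins default to the nominal sampling times (all three designs
are scheduled); quantile-edge binning is available for irregular data.
Stratification (by study, and always by drug) only partitions records —
it never changes corrected values.

The 5th–95th band of a statistic across R replicates is the closed
order-statistic interval (numpy percentile methods "lower"/"higher"):
for R = 200 it covers an exchangeable new realisation with probability
exactly 181/201 ≈ 0.9005, whereas interpolated percentiles under-cover
(~0.891). Even so, a self-consistency check against a "≥ 90%" yardstick
hovers exactly at threshold by construction — any fixed-seed realisation
of it is close to a fair coin (verified empirically at 0.899 over 30
simulated datasets).

External evaluation freezes the model and simulates a multiple-dose
design. The carbidopa covariate driving the clearance interaction can be
the **total** carbidopa dose administered over the study (the reference
convention) or the **cumulative** amount at each dose's intake. The total
convention depresses clearance from the first dose on and therefore
predicts systematically higher concentrations in the early dosing
intervals — reproducing the early over-prediction pattern that motivates
the cumulative comparison. Reported metrics are bin-wise coverage of the
observed median and the median relative prediction error.

## Known limitations

* The Laplace approximation shares FOCE's small-sample biases; no SAEM or
  adaptive Gaussian quadrature beyond the 1-eta validation oracle.
* Omega is diagonal (per-parameter CVs only; no IIV correlations).
* BLQ records retained by M6 enter the likelihood as ordinary LOD/2
  values; no censored-likelihood (M3) option.
* The cumulative-carbidopa convention treats clearance as fixed per dose
  rather than continuously time-varying.
* Mixture models for double-peak occurrence and mechanistic
  gastric-emptying feedback are out of scope by design.
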