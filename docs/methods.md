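# Methods

## Structural models

**Two-compartment linear PK.** Evaluated in closed form: the hybrid
rate constants (α, β) and central partition fractions follow from
(CL, V1, Q, V2); infusions enter by superposition of constant-rate
segment responses. The closed form is exact, so the PK-only analysis
involves no ODE error at all. A degenerate-eigenvalue guard nudges a
repeated root apart and floors an underflowed slow eigenvalue; both
only matter at parameter values far outside the physiological range
that an optimizer may visit transiently.

**QSS TMDD.** The state is (C_tot, R_tot, A2) as in the README. The
free-drug root of the QSS quadratic is computed in a cancellation-safe
form: the naive `0.5·(b + sqrt(b² + 4·Kss·Ctot))` with
b = C_tot − R_tot − K_ss loses precision when b < 0, so that branch
uses the conjugate form `2·Kss·Ctot/(sqrt(...) − b)`. This matters in
the regime this analysis lives in (baseline target ≈ 0.005 nM against
drug concentrations of 10²–10³ nM).

Integration uses a Dormand-Prince RK5(4) stepper specialised to the
3-state system and jit-compiled with numba. The system is non-stiff at
antibody time scales (all rates ≲ 0.5/day outside infusion windows,
whose fast dynamics are smooth), so the explicit method with rtol 1e-8
/ atol 1e-10 nM (simulation defaults) is accurate and fast; the
integration restarts at every infusion start/stop and lands on output
times exactly. A generic LSODA path (`engine="scipy"`) is retained and
cross-checked against the compiled integrator in the test suite;
agreement is at the 1e-6 relative level on multi-cycle regimens.
During estimation the tolerances are relaxed to rtol 1e-6 / atol 1e-9:
the objective only needs accuracy well past the optimizers' own
tolerances, and the relaxation roughly halves run time.

The peripheral state is kept as an amount (nmol), converting through
V2 only where a concentration is needed, so V1/V2 perturbations do not
leak into the state variable itself.

**Units.** All internal computation is in nM and days. The drug is
149 kDa (standard full-length IgG1); the target mass is 40 kDa, chosen
so that the baseline pair 212 ng/L = 0.0053 nM holds exactly — the
published analysis states the pair but not the mass, and VEGF165
homodimer literature values (38–46 kDa glycosylated) bracket the
back-calculated figure. Reported units (mg/L for total drug, ng/L for
free target) appear only at I/O boundaries.

## Population layer

Individual parameters are P_i = P_pop · (covariate factors) · exp(η_i)
with η ~ N(0, Ω), Ω diagonal (no η correlations are modelled).
Covariate factors: linear centred at the study median, power, or a
linear indicator contrast for genotypes (wild type as reference).
Allometric body-weight scaling uses fixed exponents, 0.75 on
clearances and 1 on volumes, referenced to 70 kg. A linear factor that
drives a parameter non-positive raises an error rather than being
clipped; the outer optimizer avoids that region through data-driven
coefficient bounds (below).

IIV magnitude is reported as CV% = 100·ω by default (the convention
that matches the published tables at these magnitudes), with the exact
log-normal CV available behind a flag. Residual error models:
proportional, additive, combined (natural scale) and additive on the
log scale; the log-additive σ is reported as ≈CV%.

## Estimation

The marginal −2 log-likelihood (OFV) is approximated subject by
subject with a Laplace expansion: OFV_i = joint(η̂) + log det H_g −
d·log 2π, where η̂ minimises the joint −2 log-likelihood of the
subject's observations and η, and H_g = Jᵀ V⁻¹ J + Ω⁻¹ is the
Gauss-Newton curvature of the linearised residual model — the standard
conditional-estimation-with-interaction linearisation (residual
variance evaluated at the individual prediction). On any model linear
in η with Gaussian error this expression is the exact marginal
likelihood, which the tests verify against the closed multivariate
normal form both on synthetic log-linear predictors and on a genuine
in-model case (a subject with only pre-dose target samples). On the
nonlinear TMDD model a Monte Carlo check puts the approximation error
at a few tenths of an OFV point per subject at the reference
parameters.

**Inner problem.** Gauss-Newton with an analytic chain-rule gradient
(exact for all four error models), forward-difference Jacobians during
iteration and a central-difference Jacobian for the final curvature, a
trust-region cap of 5 on the η-step norm, and backtracking on the true
joint objective. Modes are warm-started from the previous outer
iteration; the convergence tolerance is 1e-8 (relative gradient norm)
for reported quantities and relaxed to 1e-6 inside the outer search.
The final OFV and empirical Bayes estimates are always recomputed at
the strict settings, so reported results do not depend on the search
path. A subject whose inner step stalls contributes its best iterate
and is listed in the fit result.

**Outer problem.** L-BFGS-B on log-transformed fixed effects,
variances and residual SDs (positivity for free) and raw covariate
coefficients, with forward-difference gradients (step 1e-4) and
relative-OFV convergence at 1e-6 (1e-5 in the replicated recovery
experiments). Box bounds keep the search in the numerically meaningful
region: ±3 nats around the initial value for log-scale coordinates (a
factor of ~20 either way), ±5 for power exponents, and, for linear
covariate coefficients, the data-driven interval on which every
subject's multiplicative factor stays positive. Without the
coefficient bounds the first line search can step into the infeasible
region, where the flat failure penalty defeats the line search; with
looser log bounds it can visit hyper-stiff corners (tiny V1 with large
Q) where integration grinds — both failure modes were found and fixed
during development, and the integrator additionally fails fast on a
step-budget cap rather than grinding. Estimation draws no random
numbers; given a dataset, initials and settings it is deterministic.

**Uncertainty and diagnostics.** The covariance step inverts a
central-difference Hessian of the OFV at the optimum (covariance =
2·H⁻¹); for log-estimated quantities the log-scale SE is the
natural-scale RSE% by the delta method. A non-positive-definite
Hessian fails the step explicitly; estimates remain. η-shrinkage is
100·(1 − sd(η̂)/ω̂), ε-shrinkage 100·(1 − sd(IWRES)).

## Covariate search and randomization test

Stepwise covariate modelling: greedy forward selection (largest ΔOFV
first, threshold χ²(0.95, df)), then backward elimination at
χ²(0.99, df); genotype candidates may enter as 2-indicator groups with
2-df thresholds. Ties break by declaration order. The randomization
test shuffles whole covariate vectors between subjects (preserving
within-subject consistency), refits the full model to each shuffled
dataset, and reads the empirical 5th percentile of the null ΔOFV
distribution as the calibrated critical drop; the base model is fitted
once, to the original data.

## Predictive checks

The pcVPC multiplies each observation (and each simulated counterpart)
by bin-median population prediction / own population prediction, on the
reported-unit scale; no censoring correction is applied because the
emulated assay produced no below-quantification values. Binning is by
time after the most recent dose by default (quantile edges), with time
since first dose available. Simulated replicates re-draw η and ε on
the fitted design; population predictions are design-determined and
therefore computed once. Self-simulation coverage of the 95% bands is
part of the acceptance suite.

## Synthetic cohorts

`generate_cohort` emulates the study design: 19 patients, weight and
age from Beta distributions rescaled to the reported ranges with the
reported medians (only median and range are published; Beta is a
modelling choice giving bounded, mildly skewed draws), 58% male,
genotype frequencies from the reported counts, arms of 5 mg/kg q2w
(one subject at 10 mg/kg) and 7.5 mg/kg q3w, infusion durations
90/60/30 min over successive cycles, paired pre-/post-dose samples on
the scheduled cycles each subject completes (treatment duration drawn
per arm from the reported median/range), plus the pre-dose cycle-1
target-only sample. Genotypes are drawn independently per SNP — real
promoter-haplotype linkage is not modelled. Observation counts vary by
subject through the duration draw; the generator targets the reported
medians and ranges, not exact per-cycle attendance.

`generate_rich_cohort` is the recovery-experiment design: every
subject on the same regimen (default 6 doses of 5 mg/kg q2w), with 8
paired-analyte occasions placed in the first and the last dosing
interval — baseline (target only), end of first infusion, early
rebound points near 0.1 and 0.3 of the interval (the free-target
turnover half-life is ~1.7 days and only visible shortly after an
infusion), first trough, steady-state peak, mid-interval and trough.
Sampling a steady-state interval is essential: with a terminal
half-life longer than a dosing interval, two consecutive intervals from
time zero cannot separate clearance from distribution, whereas the
accumulated trough level pins clearance directly. Of the fixed effects,
kout is intrinsically the weakest at this design because the free
target stays largely suppressed at therapeutic exposure, which
motivates the replication policy below.

What passing recovery tests do and do not show: the synthetic cohorts
share the generating model's structure by construction, so recovery
demonstrates estimator correctness and design informativeness, not
robustness to model misspecification, assay artefacts, dropout
informativeness or haplotype structure in real data.

## Recovery experiments and their tolerances

The acceptance experiments simulate 30-subject rich-design cohorts at
the published population values (TMDD: IIV 20/22/33% on CL/V1/BM0,
log-additive residual 28%/32%; PK: IIV 23/15%, proportional 24%) and
refit from neutral round-number initials (the baseline-target initial
is taken from the data, as a modeller would). Because a single
30-subject experiment carries sampling noise of the order of the
parameters' RSEs — largest for kout — the reported estimate is the
median of three replicate experiments with derived seeds, which brings
the spread of every reported quantity comfortably inside the recovery
tolerances. Problem sizes (30 subjects, 8 occasions, 3
replicates) were chosen to make the full recovery run complete in
about 15 minutes on one CPU.

## Known limitations

* The objective is a Laplace-type approximation; exact parity with any
  specific FOCE-I implementation is not attempted, and absolute OFV
  values are not comparable across tools (ΔOFV is).
* Ω is diagonal; no inter-occasion variability; no full TMDD system or
  Michaelis-Menten/QE variants; no tumour compartment or platelet
  target pool.
* The published 42%/54% steady-state declines in free target have no
  stated evaluation time; a generic suppression-at-time query is
  provided instead of hard-coding a reading.
* The covariance step uses finite differences of an objective that
  itself contains iterative inner solves; very flat directions (e.g.
  Q and V2 under sparse designs) can fail the positive-definiteness
  check, which is reported rather than papered over.
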