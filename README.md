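# bevtmdd

Population pharmacokinetics of bevacizumab binding its soluble target
VEGF165, modelled with the quasi-steady-state (QSS) approximation of
target-mediated drug disposition (TMDD) and estimated by nonlinear
mixed-effects (NLME) maximum likelihood.

## Who this is for

Pharmacometricians and methods researchers who want a transparent,
fully scripted implementation of the classical two-step monoclonal
antibody-ligand binding analysis: a two-compartment population PK model
fitted to total-antibody concentrations, then a simultaneous QSS TMDD
fit of total antibody and free ligand. The clinical study this package
emulates (19 colorectal-cancer patients, sparse paired pre-/post-dose
sampling, three VEGF promoter SNPs as candidate covariates) was never
deposited, so the package ships a synthetic-cohort generator that
reproduces the study's design and reported population parameters,
making every stage of the analysis testable end to end.

## The model

Drug (total concentration C_tot, nM, central compartment), target
(total R_tot, nM) and the peripheral free-drug amount A2 (nmol) evolve
as

    dC_tot/dt = In(t)/V1 − (CL/V1 + Q/V1)·C − (CL_RC/V1)·R_tot·C/(K_ss + C) + (Q/V2)·A2/V1
    dR_tot/dt = k_in − k_out·R_tot − (CL_RC/V1 − k_out)·R_tot·C/(K_ss + C)
    dA2/dt    = Q·C − (Q/V2)·A2

with the free drug C the nonnegative root of
C + R_tot·C/(K_ss + C) = C_tot, complex RC = R_tot·C/(K_ss + C), free
target R = R_tot − RC, and k_in = BM0·k_out so the drug-free state is
stationary at the baseline target level BM0. K_ss = (k_int + k_off)/k_on
collapses the binding micro-constants. The complex clearance CL_RC is
tied to CL (sparse data cannot separate them).

Between-subject variability is log-normal, P_i = P_pop · exp(η_i)
(diagonal Ω); body weight scales clearances allometrically with
exponent 0.75 and volumes with exponent 1; residual error is
proportional for the PK-only step and additive on the log scale for the
simultaneous fit. The marginal likelihood is approximated per subject
by a Laplace expansion at the empirical Bayes mode with
Gauss-Newton (FOCE-with-interaction-style) curvature; model comparison
uses ΔOFV against χ² quantiles (3.84 forward / 6.64 backward for 1 df),
with a 200-shuffle randomization test to calibrate covariate
significance empirically, and prediction-corrected visual predictive
checks for model evaluation.

## Worked example

```python
from bevtmdd.diagnostics import typical_profiles
from bevtmdd.reference import TMDD_TYPICAL

profiles = typical_profiles(TMDD_TYPICAL)  # 70 kg typical patient
for name, p in profiles.items():
    print(f"{name}: suppression {p.first_dose_suppression_pct:.1f}%, "
          f"accumulation x{p.target_accumulation_ratio:.2f}")
```

prints

    5mg/kg_q2w: suppression 72.6%, accumulation x3.02
    7.5mg/kg_q3w: suppression 79.8%, accumulation x3.02

i.e. the first 90-min infusion of 5 mg/kg suppresses free VEGF165 by
73% (80% at 7.5 mg/kg), and under continued dosing the *total* target
accumulates about three-fold over its 212 ng/L baseline as drug-bound
complex builds up.

A full synthetic analysis from the shell:

    bevtmdd simulate --seed 7 --out cohort.csv
    bevtmdd fit-tmdd --data cohort.csv --out results/
    bevtmdd run --seed 7 --out results/   # whole pipeline incl. SCM, VPC

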