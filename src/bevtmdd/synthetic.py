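"""Synthetic cohort generation.

Two designs are provided:

* a study-emulating sparse design: 19 colorectal-cancer patients dosed
  5 mg/kg every 2 weeks (one of them 10 mg/kg) or 7.5 mg/kg every 3
  weeks, 90-min first infusion then 60 and 30 min, paired pre-/post-dose
  samples on scheduled cycles plus a pre-dose cycle-1 free-target sample;
* a rich design for parameter-recovery experiments: dense paired-analyte
  sampling over two dosing intervals.

Covariate distributions match the reported summaries: body weight median
70 kg (range 50-94), age median 60 y (37-73), 58% male, and the three
VEGF promoter SNP genotype frequency tables.  Weight and age are drawn
from Beta distributions rescaled to the reported range with the reported
median (only median and range are known; the family is a modelling
choice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import (
    Analyte,
    DoseEvent,
    MINUTES_PER_DAY,
    Observation,
    PatientCovariates,
    Sex,
    StudyDataset,
    Subject,
)
from .population import (
    ErrorModel,
    PopulationModelSpec,
    StructuralModel,
    individual_parameters,
)
from .structural import linear_pk_profile, simulate_tmdd
from .units import molar_to_mass

__all__ = [
    "RegimenArm",
    "CohortDesign",
    "STUDY_DESIGN",
    "TruthRecord",
    "generate_cohort",
    "simulate_observations",
    "generate_rich_cohort",
]


def _beta_params_for_median(median_frac: float, concentration: float = 5.0):
    """Shape parameters of a Beta with (approximately) the requested
    median, using the (a - 1/3)/(a + b - 2/3) median approximation."""
    a = median_frac * (concentration - 2.0 / 3.0) + 1.0 / 3.0
    b = concentration - a
    return a, b


@dataclass(frozen=True)
class RegimenArm:
    """One dosing arm: dose per kg, interval, scheduled sampling cycles
    and the treatment-duration range/median (days)."""

    name: str
    dose_mg_per_kg: float
    interval_days: float
    sampling_cycles: tuple[int, ...]
    duration_median: float
    duration_range: tuple[float, float]


@dataclass(frozen=True)
class CohortDesign:
    n_subjects: int = 19
    weight_median: float = 70.0
    weight_range: tuple[float, float] = (50.0, 94.0)
    age_median: float = 60.0
    age_range: tuple[float, float] = (37.0, 73.0)
    male_fraction: float = 11.0 / 19.0
    #: genotype frequencies, wild type / heterozygous / homozygous variant
    snp_2578: Mapping[str, float] = field(
        default_factory=lambda: {"CC": 2 / 19, "AA": 6 / 19, "CA": 11 / 19}
    )
    snp_1154: Mapping[str, float] = field(
        default_factory=lambda: {"GG": 10 / 19, "AA": 2 / 19, "GA": 7 / 19}
    )
    snp_634: Mapping[str, float] = field(
        default_factory=lambda: {"GG": 14 / 19, "CC": 1 / 19, "GC": 4 / 19}
    )
    #: infusion durations (days): first dose 90 min, second 60, later 30
    infusion_schedule: tuple[float, ...] = (
        90.0 / MINUTES_PER_DAY, 60.0 / MINUTES_PER_DAY, 30.0 / MINUTES_PER_DAY,
    )
    arms: tuple[RegimenArm, ...] = (
        RegimenArm("q2w", 5.0, 14.0, (3, 6, 8, 12, 18, 24), 127.5, (27.0, 348.0)),
        RegimenArm("q3w", 7.5, 21.0, (2, 4, 5, 8, 11), 174.0, (71.0, 251.0)),
    )
    n_q2w: int = 10  # subjects on the q2w arm; one of them at 10 mg/kg
    high_dose_mg_per_kg: float = 10.0

    def __post_init__(self) -> None:
        for name in ("snp_2578", "snp_1154", "snp_634"):
            freqs = getattr(self, name)
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies must sum to 1")
        for arm in self.arms:
            if any(b <= a for a, b in zip(arm.sampling_cycles, arm.sampling_cycles[1:])):
                raise ValueError(f"arm {arm.name}: sampling cycles must increase")


STUDY_DESIGN = CohortDesign()


def _draw_scaled_beta(rng, median, lo, hi, size):
    a, b = _beta_params_for_median((median - lo) / (hi - lo))
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def _infusion_duration(design: CohortDesign, dose_index: int) -> float:
    sched = design.infusion_schedule
    return sched[min(dose_index, len(sched) - 1)]


def generate_cohort(
    design: CohortDesign = STUDY_DESIGN, seed: int = 0
) -> StudyDataset:
    """Dataset skeleton (covariates, doses, sample times; no DV).

    Doses are dose-per-kg times body weight; each sampled cycle
    contributes a pre-dose sample and a post-dose sample at the end of
    that cycle's infusion; cycle 1 contributes a pre-dose free-target
    sample.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    if n == 0:
        return StudyDataset(())
    weights = _draw_scaled_beta(rng, design.weight_median, *design.weight_range, n)
    ages = _draw_scaled_beta(rng, design.age_median, *design.age_range, n)
    males = rng.random(n) < design.male_fraction

    def draw_genotype(freqs):
        levels = list(freqs)
        return rng.choice(levels, size=n, p=[freqs[g] for g in levels])

    g2578 = draw_genotype(design.snp_2578)
    g1154 = draw_genotype(design.snp_1154)
    g634 = draw_genotype(design.snp_634)

    n_q2w = min(design.n_q2w, n)
    arm_of = [design.arms[0]] * n_q2w + [design.arms[1]] * (n - n_q2w)
    high_dose_subject = rng.integers(0, n_q2w) if n_q2w else -1

    subjects = []
    for i in range(n):
        arm = arm_of[i]
        dose_per_kg = (
            design.high_dose_mg_per_kg if i == high_dose_subject else arm.dose_mg_per_kg
        )
        lo, hi = arm.duration_range
        duration = _draw_scaled_beta(rng, arm.duration_median, lo, hi, 1)[0]
        n_cycles = max(1, int(duration // arm.interval_days) + 1)
        amount = dose_per_kg * weights[i]
        doses = tuple(
            DoseEvent(
                time=c * arm.interval_days,
                amount=amount,
                duration=_infusion_duration(design, c),
            )
            for c in range(n_cycles)
        )
        observations = [Observation(0.0, Analyte.FREE_TARGET, None, missing=True)]
        attended = [c for c in arm.sampling_cycles if c <= n_cycles]
        for c in attended:
            t_dose = (c - 1) * arm.interval_days
            t_post = t_dose + _infusion_duration(design, c - 1)
            for analyte in (Analyte.TOTAL_DRUG, Analyte.FREE_TARGET):
                observations.append(Observation(t_dose, analyte, None, missing=True))
                observations.append(Observation(t_post, analyte, None, missing=True))
        observations.sort(key=lambda o: (o.time, o.analyte.value))
        cov = PatientCovariates(
            weight=float(weights[i]), age=float(ages[i]),
            sex=Sex.M if males[i] else Sex.F,
            snp_2578=str(g2578[i]), snp_1154=str(g1154[i]), snp_634=str(g634[i]),
        )
        subjects.append(Subject(f"S{i + 1:02d}", cov, doses, tuple(observations)))
    return StudyDataset(tuple(subjects))


def generate_rich_cohort(
    n: int,
    samples_per_subject: int = 8,
    seed: int = 0,
    dose_mg_per_kg: float = 5.0,
    interval_days: float = 14.0,
    n_cycles: int = 6,
    design: CohortDesign = STUDY_DESIGN,
) -> StudyDataset:
    """Dense-design skeleton for recovery experiments.

    Every subject receives the same ``n_cycles``-dose regimen;
    ``samples_per_subject`` paired-analyte occasions are placed inside
    two dosing intervals - the first and the last - so that both the
    initial kinetics (infusion peak, target suppression and rebound) and
    the accumulated steady state (whose troughs identify clearance: the
    terminal half-life of an IgG exceeds a single dosing interval) are
    observed.  The baseline occasion samples the free target only."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = _draw_scaled_beta(rng, design.weight_median, *design.weight_range, n)
    ages = _draw_scaled_beta(rng, design.age_median, *design.age_range, n)
    males = rng.random(n) < design.male_fraction
    dur = design.infusion_schedule[0]

    last = (n_cycles - 1) * interval_days
    dur_last = _infusion_duration(design, n_cycles - 1)
    # priority-ordered anchors: baseline, first peak and trough, early
    # rebound points (the free-target turnover half-life is on the order
    # of days, visible only shortly after an infusion), steady-state
    # peak, mid-interval and trough
    anchors = [
        0.0, dur, interval_days - 0.05,
        last + dur_last, last + interval_days - 0.05,
        0.1 * interval_days, 0.3 * interval_days,
        last + 0.5 * interval_days,
    ]
    extra = max(samples_per_subject - len(anchors), 0)
    n1 = (extra + 1) // 2
    n2 = extra - n1
    washout1 = list(np.geomspace(0.25, 0.35 * interval_days, n1)) if n1 else []
    washout2 = list(last + np.geomspace(0.25, 0.35 * interval_days, n2)) if n2 else []
    times = sorted((anchors[:samples_per_subject] + washout1 + washout2)[:samples_per_subject])

    subjects = []
    for i in range(n):
        cov = PatientCovariates(
            weight=float(weights[i]), age=float(ages[i]),
            sex=Sex.M if males[i] else Sex.F,
        )
        amount = dose_mg_per_kg * weights[i]
        doses = tuple(
            DoseEvent(c * interval_days, amount, _infusion_duration(design, c))
            for c in range(n_cycles)
        )
        observations = []
        for t in times:
            # the baseline occasion is pre-dose: no drug on board yet
            analytes = (
                (Analyte.FREE_TARGET,) if t == 0.0
                else (Analyte.TOTAL_DRUG, Analyte.FREE_TARGET)
            )
            for analyte in analytes:
                observations.append(Observation(t, analyte, None, missing=True))
        subjects.append(Subject(f"R{i + 1:03d}", cov, doses, tuple(observations)))
    return StudyDataset(tuple(subjects))


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to reproduce a simulated dataset: the generating
    spec, the seed, and the drawn random effects and residuals."""

    spec: PopulationModelSpec
    seed: int
    etas: Mapping[str, Mapping[str, float]]
    epsilons: Mapping[str, tuple[float, ...]]


def simulate_observations(
    skeleton: StudyDataset,
    spec: PopulationModelSpec,
    seed: int = 0,
    max_retries: int = 5,
) -> tuple[StudyDataset, TruthRecord]:
    """Fill a skeleton's observation slots with model-simulated DVs.

    Per subject: draw eta ~ N(0, omega2), resolve individual parameters,
    simulate the structural model over the subject's regimen, evaluate
    the analyte predictions at the sample times and apply the residual
    error on the model's scale (log-normal for ADDITIVE_LOG, truncated at
    zero for normal-scale models).  All outputs are in reported units.
    Observations of FREE_TARGET under a LINEAR_PK spec are dropped."""
    rng = np.random.default_rng(seed)
    subjects_out = []
    all_etas: dict[str, dict[str, float]] = {}
    all_eps: dict[str, tuple[float, ...]] = {}
    for subject in skeleton:
        for attempt in range(max_retries):
            eta = {
                p: float(rng.normal(0.0, math.sqrt(spec.omega2[p])))
                for p in spec.eta_names
            }
            try:
                new_subject, eps = _simulate_subject(subject, spec, eta, rng)
            except (RuntimeError, FloatingPointError, ValueError):
                continue
            break
        else:
            raise RuntimeError(
                f"simulation failed for subject {subject.id} after {max_retries} retries"
            )
        subjects_out.append(new_subject)
        all_etas[subject.id] = eta
        all_eps[subject.id] = eps
    dataset = StudyDataset(tuple(subjects_out))
    return dataset, TruthRecord(spec=spec, seed=seed, etas=all_etas, epsilons=all_eps)


def _simulate_subject(subject, spec, eta, rng):
    params = individual_parameters(spec, spec.theta, eta, subject.covariates)
    obs = list(subject.observations)
    if spec.structural is StructuralModel.LINEAR_PK:
        obs = [o for o in obs if o.analyte is Analyte.TOTAL_DRUG]
        times = np.array([o.time for o in obs])
        pred = {Analyte.TOTAL_DRUG: linear_pk_profile(
            params, subject.doses, times, spec.mw.mw_drug
        )}
        pred_at = lambda j, o: pred[o.analyte][j]
    else:
        grid = np.unique([o.time for o in obs])
        traj = simulate_tmdd(params, subject.doses, grid, mw_drug=spec.mw.mw_drug)
        series = {Analyte.TOTAL_DRUG: traj.Ctot, Analyte.FREE_TARGET: traj.R}
        index = {t: i for i, t in enumerate(grid)}
        pred_at = lambda j, o: series[o.analyte][index[o.time]]

    mw = {Analyte.TOTAL_DRUG: spec.mw.mw_drug, Analyte.FREE_TARGET: spec.mw.mw_target}
    new_obs = []
    eps_draws = []
    for j, o in enumerate(obs):
        f = float(pred_at(j, o))
        err = spec.error[o.analyte]
        eps = float(rng.normal())
        eps_draws.append(eps)
        if err.model is ErrorModel.ADDITIVE_LOG:
            if f <= 0:
                raise RuntimeError("non-positive prediction under log-scale error")
            dv_nm = f * math.exp(err.sigma * eps)
        elif err.model is ErrorModel.PROPORTIONAL:
            dv_nm = f * (1.0 + err.sigma * eps)
        elif err.model is ErrorModel.ADDITIVE:
            dv_nm = f + err.sigma_add * eps
        else:
            dv_nm = f + math.sqrt(err.sigma_add**2 + (err.sigma * f) ** 2) * eps
        if dv_nm <= 0:
            raise RuntimeError("simulated observation fell at or below zero")
        value = molar_to_mass(dv_nm, mw[o.analyte], o.analyte.reported_unit)
        new_obs.append(Observation(o.time, o.analyte, value, missing=False))
    from dataclasses import replace

    return replace(subject, observations=tuple(new_obs)), tuple(eps_draws)
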