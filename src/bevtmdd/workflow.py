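"""Two-step analysis orchestration.

The analysis proceeds as the study did: step 1 fits the two-compartment
PK model to the total-drug data alone; step 2 fits the QSS TMDD model to
both analytes simultaneously, with the complex clearance tied to CL,
additive-log residual errors and allometric body-weight scaling on all
clearance and volume parameters, using the step-1 estimates as initial
values for the shared PK parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dataset import Analyte, StudyDataset, read_dataset, write_dataset
from .estimation import FitResult, ObjectiveSettings, fit, shrinkage, standard_errors
from .population import (
    ErrorModel,
    PopulationModelSpec,
    ResidualErrorSpec,
    StructuralModel,
    allometric_relations,
    iiv_cv_percent,
)
from .reference import REFERENCE_WEIGHT_KG
from .units import DEFAULT_MOLAR_CONSTANTS, mass_to_molar, molar_to_mass

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_step1", "run_step2", "run_all", "fit_report"]


@dataclass
class AnalysisConfig:
    """Configuration of the full pipeline.

    Exactly one data source: either ``dataset_path`` (NONMEM-style CSV)
    or ``synthetic=True`` to generate the study-emulating cohort.  All
    stochastic stages (synthetic data, VPC) draw from ``seed``."""

    output_dir: str = "bevtmdd_output"
    dataset_path: str | None = None
    synthetic: bool = False
    n_subjects: int | None = None  # synthetic cohort size override
    seed: int = 1
    n_vpc_sim: int = 1000
    vpc_bins: int = 6
    run_scm: bool = True
    run_randtest: bool = True
    compute_se: bool = True
    n_permutations: int = 200
    settings: ObjectiveSettings = field(default_factory=ObjectiveSettings)

    def __post_init__(self) -> None:
        if (self.dataset_path is None) == (not self.synthetic):
            raise ValueError(
                "exactly one data source: dataset_path or synthetic=True"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        settings = ObjectiveSettings(**raw.pop("settings", {}))
        return cls(settings=settings, **raw)


def _load_dataset(config: AnalysisConfig) -> StudyDataset:
    if config.dataset_path is not None:
        return read_dataset(config.dataset_path)
    from .reference import tmdd_reference_spec
    from .synthetic import STUDY_DESIGN, generate_cohort, simulate_observations

    design = STUDY_DESIGN
    if config.n_subjects is not None:
        design = dataclasses.replace(design, n_subjects=config.n_subjects,
                                     n_q2w=(config.n_subjects + 1) // 2)
    skeleton = generate_cohort(design, seed=config.seed)
    dataset, _ = simulate_observations(
        skeleton, tmdd_reference_spec(), seed=config.seed + 1
    )
    return dataset


def _step1_spec(initials: dict[str, float] | None = None) -> PopulationModelSpec:
    theta = initials or {"CL": 0.2, "V1": 4.0, "Q": 0.5, "V2": 4.0}
    return PopulationModelSpec(
        structural=StructuralModel.LINEAR_PK,
        theta=theta,
        omega2={"CL": 0.1, "V1": 0.1},
        error={Analyte.TOTAL_DRUG: ResidualErrorSpec(ErrorModel.PROPORTIONAL, 0.2)},
        relations=tuple(allometric_relations(
            ["CL", "V1", "Q", "V2"], REFERENCE_WEIGHT_KG
        )),
    )


def run_step1(
    config: AnalysisConfig, dataset: StudyDataset | None = None
) -> FitResult:
    """Step 1: population PK of the total drug alone (proportional
    error, IIV on CL and V1, allometric weight scaling)."""
    dataset = dataset if dataset is not None else _load_dataset(config)
    pk_data = dataset.with_analytes([Analyte.TOTAL_DRUG])
    if pk_data.n_observations == 0:
        raise ValueError("step 1 requires TOTAL_DRUG observations")
    result = fit(_step1_spec(), pk_data, config.settings)
    return result


def run_step2(
    config: AnalysisConfig,
    step1: FitResult,
    dataset: StudyDataset | None = None,
) -> FitResult:
    """Step 2: simultaneous QSS TMDD fit of both analytes.

    PK initials come from the step-1 estimates; the baseline-target
    initial is the median pre-dose free-target observation; CL_RC is
    tied to CL; IIV on CL, V1 and BM0; additive-log error per analyte."""
    dataset = dataset if dataset is not None else _load_dataset(config)
    has = {o.analyte for s in dataset for o in s.observations if not o.missing}
    if Analyte.FREE_TARGET not in has or Analyte.TOTAL_DRUG not in has:
        raise ValueError(
            "step 2 requires both TOTAL_DRUG and FREE_TARGET observations"
        )
    baselines = [
        o.value for s in dataset for o in s.observations
        if o.analyte is Analyte.FREE_TARGET and not o.missing
        and o.time <= min(d.time for d in s.doses)
    ]
    bm0_init = mass_to_molar(
        float(np.median(baselines)) if baselines else 200.0,
        DEFAULT_MOLAR_CONSTANTS.mw_target, "ng/L",
    )
    spec = PopulationModelSpec(
        structural=StructuralModel.QSS_TMDD,
        theta={
            "CL": step1.theta["CL"], "V1": step1.theta["V1"],
            "Q": step1.theta["Q"], "V2": step1.theta["V2"],
            "BM0": bm0_init, "kout": 0.2, "Kss": 100.0,
        },
        omega2={"CL": 0.04, "V1": 0.04, "BM0": 0.1},
        error={
            Analyte.TOTAL_DRUG: ResidualErrorSpec(ErrorModel.ADDITIVE_LOG, 0.3),
            Analyte.FREE_TARGET: ResidualErrorSpec(ErrorModel.ADDITIVE_LOG, 0.3),
        },
        relations=tuple(allometric_relations(
            ["CL", "V1", "Q", "V2"], REFERENCE_WEIGHT_KG
        )),
    )
    return fit(spec, dataset, config.settings)


def fit_report(result: FitResult, title: str) -> str:
    """Human-readable estimates table (typical value, IIV CV%, residual
    error), mirroring the conventional population-PK report layout."""
    lines = [title, "=" * len(title), ""]
    lines.append(f"OFV: {result.ofv:.3f}   converged: {result.converged}   "
                 f"subjects: {result.n_subjects}   observations: {result.n_obs}")
    if result.flagged_subjects:
        lines.append(f"flagged subjects (inner step): {result.flagged_subjects}")
    lines.append("")
    lines.append(f"{'parameter':<12} {'typical':>12} {'RSE%':>8}")
    rse = result.rse or {}
    for p, v in result.theta.items():
        shown = v
        if p == "BM0":
            shown = molar_to_mass(v, result.spec.mw.mw_target, "ng/L")
            lines.append(f"{'BM0 ng/L':<12} {shown:>12.4g} "
                         f"{rse.get(p, float('nan')):>8.3g}")
            continue
        lines.append(f"{p:<12} {shown:>12.4g} {rse.get(p, float('nan')):>8.3g}")
    for name, value in result.relation_values.items():
        rel = next(r for r in result.spec.relations if r.name == name)
        tag = " (fixed)" if rel.fixed else ""
        lines.append(f"{name:<24} {value:>12.4g}{tag}")
    lines.append("")
    lines.append(f"{'IIV':<12} {'CV%':>8} {'shrink%':>9}")
    shr = result.eta_shrinkage or {}
    for p, w2 in result.omega2.items():
        lines.append(f"{p:<12} {iiv_cv_percent(w2):>8.3g} "
                     f"{shr.get(p, float('nan')):>9.3g}")
    lines.append("")
    eps = result.eps_shrinkage or {}
    for analyte, err in result.sigma.items():
        label = f"sigma_{analyte.name}"
        lines.append(
            f"{label:<24} {err.model.value:<16} {100 * err.sigma:>6.3g}% "
            f"(eps-shrink {eps.get(analyte, float('nan')):.3g}%)"
        )
    return "\n".join(lines)


def run_all(config: AnalysisConfig) -> dict:
    """Full pipeline: data, step-1 PK fit, step-2 TMDD fit, optional
    covariate search and randomization test, pcVPC, typical profiles.
    Every artifact lands under ``config.output_dir`` with a manifest."""
    from .covariates import randomization_test, scm
    from .diagnostics import pcvpc, typical_profiles
    from .population import CovariateRelation, RelationForm
    from .structural import TMDDParameters

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def save(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        manifest[name] = hashlib.sha256(text.encode()).hexdigest()

    dataset = _load_dataset(config)
    write_dataset(dataset, out / "dataset.csv")
    manifest["dataset.csv"] = hashlib.sha256(
        (out / "dataset.csv").read_bytes()
    ).hexdigest()

    step1 = run_step1(config, dataset)
    pk_data = dataset.with_analytes([Analyte.TOTAL_DRUG])
    if config.compute_se:
        standard_errors(step1, pk_data)
    step1.eta_shrinkage, step1.eps_shrinkage = shrinkage(step1, pk_data)
    save("step1_pk_fit.txt", fit_report(step1, "Step 1: population PK model"))

    step2 = run_step2(config, step1, dataset)
    if config.compute_se:
        standard_errors(step2, dataset)
    step2.eta_shrinkage, step2.eps_shrinkage = shrinkage(step2, dataset)
    save("step2_tmdd_fit.txt", fit_report(step2, "Step 2: QSS TMDD model"))

    if config.run_scm:
        candidates = [
            CovariateRelation("Kss", "snp_2578", RelationForm.LINEAR_CATEGORICAL,
                              0.0, level="AA"),
            CovariateRelation("Kss", "snp_634", RelationForm.LINEAR_CATEGORICAL,
                              0.0, level="GC"),
            CovariateRelation("BM0", "age", RelationForm.LINEAR_CENTERED,
                              0.0, reference=60.0),
        ]
        final_spec, log = scm(step2.spec, dataset, candidates,
                              settings=config.settings)
        save("scm.txt", log.table())

    if config.run_randtest:
        rel = CovariateRelation("Kss", "snp_2578", RelationForm.LINEAR_CATEGORICAL,
                                0.0, level="AA")
        full = PopulationModelSpec(
            step2.spec.structural, dict(step2.spec.theta),
            dict(step2.spec.omega2), dict(step2.spec.error),
            tuple(step2.spec.relations) + (rel,), step2.spec.mw,
        )
        rt = randomization_test(
            step2.spec, full, dataset, n_perm=config.n_permutations,
            seed=config.seed + 2, settings=config.settings,
        )
        save("randomization_test.txt", json.dumps({
            "observed_delta_ofv": rt.observed_delta_ofv,
            "critical_drop_5pct": rt.critical_drop_5pct,
            "attained_significance": rt.attained_significance,
            "n_failed": rt.n_failed,
        }, indent=2))

    vpc = pcvpc(step2, dataset, n_sim=config.n_vpc_sim, bins=config.vpc_bins,
                seed=config.seed + 3)
    vpc_rows = []
    for analyte, res in vpc.items():
        for b in range(len(res.bin_mid)):
            row = {"analyte": analyte.name, "bin_mid": float(res.bin_mid[b]),
                   "n": int(res.n_per_bin[b])}
            for q in (10, 50, 90):
                row[f"obs_p{q}"] = float(res.observed[q][b])
                row[f"lo_p{q}"] = float(res.band_low[q][b])
                row[f"hi_p{q}"] = float(res.band_high[q][b])
            vpc_rows.append(row)
    import pandas as pd

    pd.DataFrame(vpc_rows).to_csv(out / "pcvpc.csv", index=False)
    manifest["pcvpc.csv"] = hashlib.sha256(
        (out / "pcvpc.csv").read_bytes()
    ).hexdigest()

    typical = TMDDParameters(
        CL=step2.theta["CL"], V1=step2.theta["V1"], Q=step2.theta["Q"],
        V2=step2.theta["V2"], CL_RC=step2.theta["CL"],
        BM0=step2.theta["BM0"], kout=step2.theta["kout"],
        Kss=step2.theta["Kss"],
    )
    profiles = typical_profiles(typical)
    prof_summary = {
        name: {
            "first_dose_suppression_pct": p.first_dose_suppression_pct,
            "target_accumulation_ratio": p.target_accumulation_ratio,
        }
        for name, p in profiles.items()
    }
    save("typical_profiles.txt", json.dumps(prof_summary, indent=2))

    save("config.txt", json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(config).items()}, indent=2
    ))
    save("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return {"step1": step1, "step2": step2, "manifest": manifest,
            "profiles": prof_summary}
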