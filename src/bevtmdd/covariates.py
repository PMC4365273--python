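"""Stepwise covariate model building and randomization-test calibration.

Forward selection adds, one at a time, the candidate relation giving the
largest significant OFV drop (default threshold 3.84, the chi-square
95th percentile for 1 df); backward elimination then removes relations
whose deletion raises the OFV by less than the stricter backward
threshold (default 6.64, the 99th percentile).  Multi-df candidates use
the matching chi-square quantile.

The randomization test calibrates the forward threshold empirically:
the covariate column is shuffled between subjects a number of times and
the full model refitted to each shuffled dataset; the empirical 5th
percentile of the null Delta OFV distribution is the drop actually
required for 5% significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import StudyDataset
from .estimation import FitResult, ObjectiveSettings, chi2_quantile, fit
from .population import CovariateRelation, PopulationModelSpec

logger = logging.getLogger(__name__)

__all__ = ["ScmStep", "ScmLog", "scm", "RandTestResult", "randomization_test"]


@dataclass(frozen=True)
class ScmStep:
    phase: str  # "forward" or "backward"
    candidate: str  # relation name(s), comma-joined for multi-df groups
    delta_ofv: float
    threshold: float
    decision: str  # "included" / "removed" / "rejected" / "kept" / "failed"


@dataclass
class ScmLog:
    steps: list[ScmStep] = field(default_factory=list)
    final_spec: PopulationModelSpec | None = None
    final_ofv: float | None = None

    def table(self) -> str:
        lines = [f"{'phase':<9} {'candidate':<28} {'dOFV':>10} {'thresh':>8} decision"]
        for s in self.steps:
            lines.append(
                f"{s.phase:<9} {s.candidate:<28} {s.delta_ofv:>10.3f} "
                f"{s.threshold:>8.2f} {s.decision}"
            )
        return "\n".join(lines)


def _with_relations(
    spec: PopulationModelSpec, relations: Sequence[CovariateRelation]
) -> PopulationModelSpec:
    return PopulationModelSpec(
        spec.structural, dict(spec.theta), dict(spec.omega2), dict(spec.error),
        tuple(relations), spec.mw,
    )


def scm(
    base_spec: PopulationModelSpec,
    dataset: StudyDataset,
    candidates: Sequence[Sequence[CovariateRelation] | CovariateRelation],
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
    settings: ObjectiveSettings = ObjectiveSettings(),
    fix: set[str] | None = None,
) -> tuple[PopulationModelSpec, ScmLog]:
    """Greedy forward-selection / backward-elimination covariate search.

    Each candidate is one relation or a group of relations tested jointly
    (df = group size; e.g. two indicator contrasts of one genotype).
    Deterministic: ties in Delta OFV break by declaration order."""
    groups: list[tuple[CovariateRelation, ...]] = [
        (c,) if isinstance(c, CovariateRelation) else tuple(c) for c in candidates
    ]
    log = ScmLog()
    current = base_spec
    base_fit = fit(current, dataset, settings, fix=fix)
    current_ofv = base_fit.ofv
    remaining = list(groups)
    included: list[tuple[CovariateRelation, ...]] = []

    # forward phase
    while remaining:
        scored: list[tuple[float, int, FitResult]] = []
        for gi, group in enumerate(remaining):
            trial = _with_relations(current, tuple(current.relations) + group)
            try:
                trial_fit = fit(trial, dataset, settings, fix=fix)
            except Exception as exc:  # candidate fit failure: skip, log
                logger.warning("candidate %s failed: %s", _group_name(group), exc)
                log.steps.append(ScmStep(
                    "forward", _group_name(group), float("nan"),
                    chi2_quantile(1 - forward_alpha, len(group)), "failed",
                ))
                continue
            scored.append((current_ofv - trial_fit.ofv, gi, trial_fit))
        if not scored:
            break
        best_drop, best_gi, best_fit = max(scored, key=lambda s: (s[0], -s[1]))
        group = remaining[best_gi]
        threshold = chi2_quantile(1 - forward_alpha, len(group))
        if best_drop > threshold:
            log.steps.append(ScmStep(
                "forward", _group_name(group), best_drop, threshold, "included"
            ))
            included.append(group)
            current = best_fit.spec
            current_ofv = best_fit.ofv
            remaining.pop(best_gi)
        else:
            for drop, gi, _ in sorted(scored, key=lambda s: -s[0]):
                log.steps.append(ScmStep(
                    "forward", _group_name(remaining[gi]), drop,
                    chi2_quantile(1 - forward_alpha, len(remaining[gi])), "rejected",
                ))
            break

    # backward phase
    changed = True
    while changed and included:
        changed = False
        worst: tuple[float, int, FitResult] | None = None
        for gi, group in enumerate(included):
            names = {r.name for r in group}
            reduced = _with_relations(
                current, tuple(r for r in current.relations if r.name not in names)
            )
            reduced_fit = fit(reduced, dataset, settings, fix=fix)
            rise = reduced_fit.ofv - current_ofv
            if worst is None or rise < worst[0]:
                worst = (rise, gi, reduced_fit)
        rise, gi, reduced_fit = worst
        group = included[gi]
        threshold = chi2_quantile(1 - backward_alpha, len(group))
        if rise < threshold:
            log.steps.append(ScmStep(
                "backward", _group_name(group), rise, threshold, "removed"
            ))
            included.pop(gi)
            current = reduced_fit.spec
            current_ofv = reduced_fit.ofv
            changed = True
        else:
            log.steps.append(ScmStep(
                "backward", _group_name(group), rise, threshold, "kept"
            ))
    log.final_spec = current
    log.final_ofv = current_ofv
    return current, log


def _group_name(group: Sequence[CovariateRelation]) -> str:
    return ",".join(r.name for r in group)


@dataclass
class RandTestResult:
    observed_delta_ofv: float
    permuted_delta_ofv: np.ndarray
    critical_drop_5pct: float
    attained_significance: float
    n_failed: int

    @property
    def significant(self) -> bool:
        return self.observed_delta_ofv <= self.critical_drop_5pct


def _shuffle_covariates(dataset: StudyDataset, rng) -> StudyDataset:
    """Permute whole covariate vectors between subjects (within-subject
    consistency preserved)."""
    order = rng.permutation(len(dataset))
    covs = [s.covariates for s in dataset]
    return StudyDataset(tuple(
        replace(s, covariates=covs[order[i]]) for i, s in enumerate(dataset)
    ))


def randomization_test(
    base_spec: PopulationModelSpec,
    full_spec: PopulationModelSpec,
    dataset: StudyDataset,
    n_perm: int = 200,
    seed: int = 0,
    settings: ObjectiveSettings = ObjectiveSettings(),
    fix: set[str] | None = None,
) -> RandTestResult:
    """Permutation calibration of the covariate inclusion test.

    ``full_spec`` must be ``base_spec`` plus exactly the tested
    relation(s).  The base model is fitted once to the original data; the
    full model is fitted to the original and to each of ``n_perm``
    datasets with covariate vectors shuffled between subjects.  The
    empirical 5th percentile of the null Delta OFV = OFV_full - OFV_base
    distribution is the critical drop; failed permutation fits are
    excluded and counted."""
    rng = np.random.default_rng(seed)
    base_fit = fit(base_spec, dataset, settings, fix=fix)
    full_fit = fit(full_spec, dataset, settings, fix=fix)
    observed = full_fit.ofv - base_fit.ofv

    deltas = []
    n_failed = 0
    for _ in range(n_perm):
        shuffled = _shuffle_covariates(dataset, rng)
        try:
            full_p = fit(full_spec, shuffled, settings, fix=fix)
        except Exception as exc:
            logger.warning("permutation fit failed: %s", exc)
            n_failed += 1
            continue
        deltas.append(full_p.ofv - base_fit.ofv)
    deltas = np.array(deltas)
    critical = float(np.percentile(deltas, 5.0)) if len(deltas) else float("nan")
    attained = float(np.mean(deltas <= observed)) if len(deltas) else float("nan")
    return RandTestResult(
        observed_delta_ofv=float(observed),
        permuted_delta_ofv=deltas,
        critical_drop_5pct=critical,
        attained_significance=attained,
        n_failed=n_failed,
    )
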