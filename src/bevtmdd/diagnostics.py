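"""Model evaluation: pcVPC, goodness-of-fit residuals, typical profiles.

The prediction-corrected visual predictive check (pcVPC) normalises each
observation and each simulated counterpart by the ratio of its bin's
median population prediction to its own population prediction, then
compares observed percentiles (10/50/90) per bin with confidence bands
of the same percentiles across simulated datasets.  No lower-bound
(censoring) correction is applied - the data contain no
below-quantification values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import Analyte, DoseEvent, StudyDataset
from .estimation import FitResult, _moments, _predict_f, _SubjectData
from .population import individual_parameters
from .structural import (
    SimulationTrajectory,
    TMDDParameters,
    first_dose_suppression,
    target_accumulation_profile,
)
from .dataset import MINUTES_PER_DAY
from .synthetic import simulate_observations

logger = logging.getLogger(__name__)

__all__ = ["PcVpcResult", "pcvpc", "gof_residuals", "typical_profiles",
           "plot_pcvpc", "plot_trajectory"]


@dataclass
class PcVpcResult:
    """Per-analyte pcVPC summary.  All arrays are indexed by bin."""

    analyte: Analyte
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    observed: dict[int, np.ndarray]  # percentile -> per-bin observed value
    band_low: dict[int, np.ndarray]  # percentile -> lower 95% CI from simulation
    band_high: dict[int, np.ndarray]
    n_sim: int
    unreliable: bool = False

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside the simulated 95% band."""
        inside = total = 0
        for q in self.observed:
            ok = (self.observed[q] >= self.band_low[q]) & (
                self.observed[q] <= self.band_high[q]
            )
            inside += int(np.sum(ok))
            total += len(ok)
        return inside / total if total else float("nan")


def _population_predictions(spec, fit_result, dataset):
    """Population (eta = 0) predictions, reported-unit scale, per obs row."""
    rows = []  # (subject_id, time, analyte, dv, pred)
    from .units import molar_to_mass

    mw = {Analyte.TOTAL_DRUG: spec.mw.mw_drug, Analyte.FREE_TARGET: spec.mw.mw_target}
    for subject in dataset:
        data = _SubjectData(subject, spec)
        params = individual_parameters(
            spec, fit_result.theta, {}, subject.covariates, fit_result.relation_values
        )
        f = _predict_f(data, spec, params, fit_result.settings)
        for j in range(len(data)):
            a = data.analytes[j]
            rows.append((
                subject.id, float(data.times[j]), a,
                molar_to_mass(data.dv_nm[j], mw[a], a.reported_unit),
                molar_to_mass(float(f[j]), mw[a], a.reported_unit),
            ))
    return rows


def _reported_dvs(dataset: StudyDataset, spec) -> list[float]:
    """Non-missing DVs in reported units, in canonical row order."""
    from .units import molar_to_mass

    mw = {Analyte.TOTAL_DRUG: spec.mw.mw_drug, Analyte.FREE_TARGET: spec.mw.mw_target}
    out = []
    for subject in dataset:
        data = _SubjectData(subject, spec)
        for j in range(len(data)):
            a = data.analytes[j]
            out.append(molar_to_mass(float(data.dv_nm[j]), mw[a], a.reported_unit))
    return out


def _time_after_dose(subject_doses: Mapping[str, Sequence], sid, t):
    starts = [d.time for d in subject_doses[sid] if d.time <= t]
    return t - max(starts) if starts else t


def pcvpc(
    fit_result: FitResult,
    dataset: StudyDataset,
    n_sim: int = 1000,
    bins: int | Sequence[float] = 6,
    seed: int = 0,
    time_scale: str = "time_after_dose",  # or "time"
) -> dict[Analyte, PcVpcResult]:
    """Prediction-corrected VPC of a fitted model.

    Simulates ``n_sim`` replicates of the dataset design from the fitted
    model (re-drawing eta and epsilon), bins observations on
    ``time_scale`` (quantile bins when ``bins`` is an int), applies the
    median-normalisation prediction correction within each bin, and
    returns observed 10/50/90th percentiles with their 95% simulation
    bands."""
    spec = fit_result.spec
    if n_sim < 20:
        logger.warning("pcVPC with n_sim=%d: bands are unreliable", n_sim)
    # skeleton keeps exactly the non-missing rows so simulated replicates
    # align row-for-row with the observed records
    skeleton = StudyDataset(tuple(
        replace(s, observations=tuple(
            replace(o, value=None, missing=True)
            for o in s.observations if not o.missing
        ))
        for s in dataset
    ))
    doses_of = {s.id: s.doses for s in dataset}

    obs_rows = _population_predictions(spec, fit_result, dataset)
    # population predictions depend on the design only, so each simulated
    # replicate reuses them; only the DVs differ
    sim_dvs = []
    rng_seed = np.random.default_rng(seed)
    for k in range(n_sim):
        sim_ds, _ = simulate_observations(
            skeleton, spec, seed=int(rng_seed.integers(2**31))
        )
        sim_dvs.append(_reported_dvs(sim_ds, spec))
    sim_rows = [
        [(r[0], r[1], r[2], dv, r[4]) for r, dv in zip(obs_rows, dvs)]
        for dvs in sim_dvs
    ]

    results = {}
    percentiles = (10, 50, 90)
    analytes = sorted({r[2] for r in obs_rows}, key=lambda a: a.value)
    for analyte in analytes:
        o = [r for r in obs_rows if r[2] is analyte]
        x = np.array([
            _time_after_dose(doses_of, r[0], r[1]) if time_scale == "time_after_dose"
            else r[1]
            for r in o
        ])
        dv = np.array([r[3] for r in o])
        pred = np.array([r[4] for r in o])
        if isinstance(bins, int):
            qs = np.linspace(0, 100, bins + 1)
            edges = np.unique(np.percentile(x, qs))
        else:
            edges = np.asarray(bins, float)
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)

        bin_median_pred = np.array([
            np.median(pred[idx == b]) if np.any(idx == b) else np.nan
            for b in range(len(edges) - 1)
        ])
        pc_obs = dv * bin_median_pred[idx] / pred

        obs_pct = {q: np.full(len(edges) - 1, np.nan) for q in percentiles}
        low = {q: np.full(len(edges) - 1, np.nan) for q in percentiles}
        high = {q: np.full(len(edges) - 1, np.nan) for q in percentiles}
        n_per_bin = np.array([int(np.sum(idx == b)) for b in range(len(edges) - 1)])

        # simulated replicates: same design, same binning and correction
        sim_pct = {q: [] for q in percentiles}
        for rows in sim_rows:
            s = [r for r in rows if r[2] is analyte]
            sdv = np.array([r[3] for r in s])
            spred = np.array([r[4] for r in s])
            pc_sim = sdv * bin_median_pred[idx] / spred
            for q in percentiles:
                sim_pct[q].append([
                    np.percentile(pc_sim[idx == b], q) if n_per_bin[b] else np.nan
                    for b in range(len(edges) - 1)
                ])
        for q in percentiles:
            arr = np.array(sim_pct[q])
            for b in range(len(edges) - 1):
                if not n_per_bin[b]:
                    logger.warning("dropping empty bin %d", b)
                    continue
                obs_pct[q][b] = np.percentile(pc_obs[idx == b], q)
                low[q][b] = np.percentile(arr[:, b], 2.5)
                high[q][b] = np.percentile(arr[:, b], 97.5)

        results[analyte] = PcVpcResult(
            analyte=analyte, bin_edges=edges,
            bin_mid=0.5 * (edges[:-1] + edges[1:]), n_per_bin=n_per_bin,
            observed=obs_pct, band_low=low, band_high=high,
            n_sim=n_sim, unreliable=n_sim < 20,
        )
    return results


def gof_residuals(fit_result: FitResult, dataset: StudyDataset):
    """Goodness-of-fit table: one row per observation with population
    prediction (PRED), individual prediction (IPRED), IWRES and the
    population weighted residual (WRES at eta = 0), on the likelihood
    scale of each analyte's error model."""
    import pandas as pd

    spec = fit_result.spec
    rows = []
    for subject in dataset:
        data = _SubjectData(subject, spec)
        pop_params = individual_parameters(
            spec, fit_result.theta, {}, subject.covariates, fit_result.relation_values
        )
        ind_params = individual_parameters(
            spec, fit_result.theta, fit_result.etas[subject.id],
            subject.covariates, fit_result.relation_values,
        )
        f_pop = _predict_f(data, spec, pop_params, fit_result.settings)
        f_ind = _predict_f(data, spec, ind_params, fit_result.settings)
        m_pop, v_pop, _, _ = _moments(data, spec, f_pop)
        m_ind, v_ind, _, _ = _moments(data, spec, f_ind)
        for j in range(len(data)):
            rows.append({
                "id": subject.id,
                "time": float(data.times[j]),
                "analyte": data.analytes[j].name,
                "dv": float(data.dv_t[j]),
                "pred": float(m_pop[j]),
                "ipred": float(m_ind[j]),
                "iwres": float((data.dv_t[j] - m_ind[j]) / math.sqrt(v_ind[j])),
                "wres_pop": float((data.dv_t[j] - m_pop[j]) / math.sqrt(v_pop[j])),
            })
    return pd.DataFrame(rows)


def plot_pcvpc(results: Mapping[Analyte, PcVpcResult], path=None):
    """pcVPC panels (one per analyte): observed 10/50/90th percentile
    lines over the shaded 95% simulation bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(6 * len(results), 4),
                             squeeze=False)
    for ax, (analyte, r) in zip(axes[0], results.items()):
        for q, style in ((10, "--"), (50, "-"), (90, "--")):
            ax.fill_between(r.bin_mid, r.band_low[q], r.band_high[q],
                            alpha=0.25, color="tab:blue", linewidth=0)
            ax.plot(r.bin_mid, r.observed[q], style, color="black")
        ax.set_yscale("log")
        ax.set_xlabel("time after dose (days)")
        ax.set_ylabel(f"{analyte.name.lower()} ({analyte.reported_unit}), "
                      "prediction-corrected")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_trajectory(traj: SimulationTrajectory, path=None):
    """Typical-profile panels: total drug, free target, total target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(15, 4))
    for ax, (label, series) in zip(axes, (
        ("total drug (nM)", traj.Ctot),
        ("free target (nM)", traj.R),
        ("total target (nM)", traj.Rtot),
    )):
        ax.plot(traj.times, series)
        ax.set_xlabel("time (days)")
        ax.set_ylabel(label)
        ax.set_yscale("log")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass(frozen=True)
class TypicalProfileSummary:
    regimen: str
    trajectory: SimulationTrajectory
    first_dose_suppression_pct: float
    target_accumulation_ratio: float  # asymptote / baseline


def typical_profiles(
    params: TMDDParameters,
    weight: float = 70.0,
    regimens: Mapping[str, tuple[float, float]] | None = None,
    n_cycles: int = 10,
    infusion_minutes: float = 90.0,
    mw_drug: float | None = None,
) -> dict[str, TypicalProfileSummary]:
    """Typical-patient simulations (eta = 0) for a set of regimens.

    ``regimens`` maps names to (dose mg/kg, interval days); defaults to
    the two study regimens 5 mg/kg q2w and 7.5 mg/kg q3w.  Returns, per
    regimen, the full trajectory over ``n_cycles`` dosing cycles, the
    first-dose free-target suppression and the total-target accumulation
    ratio relative to baseline."""
    from .units import DEFAULT_MOLAR_CONSTANTS

    mw = mw_drug if mw_drug is not None else DEFAULT_MOLAR_CONSTANTS.mw_drug
    if regimens is None:
        regimens = {"5mg/kg_q2w": (5.0, 14.0), "7.5mg/kg_q3w": (7.5, 21.0)}
    dur = infusion_minutes / MINUTES_PER_DAY
    out = {}
    for name, (dose_per_kg, interval) in regimens.items():
        amount = dose_per_kg * weight
        doses = [DoseEvent(i * interval, amount, dur) for i in range(n_cycles)]
        horizon = n_cycles * interval
        traj, asymptote = target_accumulation_profile(
            params, doses, horizon, mw_drug=mw
        )
        out[name] = TypicalProfileSummary(
            regimen=name,
            trajectory=traj,
            first_dose_suppression_pct=first_dose_suppression(
                params, amount, dur, mw_drug=mw
            ),
            target_accumulation_ratio=asymptote / params.BM0,
        )
    return out
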