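"""Deterministic concentration models.

Two structural models are provided:

* a two-compartment linear PK model with first-order elimination,
  evaluated in closed form (bi-exponential impulse response, infusions by
  superposition);
* the quasi-steady-state (QSS) target-mediated drug disposition (TMDD)
  model for an antibody binding a soluble target.  Under QSS the free
  drug C, free target R and complex RC equilibrate instantaneously with
  the slowly-varying totals, so the state reduces to total drug in the
  central compartment (Ctot, nM), total target (Rtot, nM) and the free
  drug amount in the peripheral compartment (A2, nmol):

      dCtot/dt = In(t)/V1 - (CL/V1 + Q/V1) C - (CL_RC/V1) Rtot C/(Kss+C)
                 + (Q/V2) A2 / V1
      dRtot/dt = kin - kout Rtot - (CL_RC/V1 - kout) Rtot C/(Kss+C)
      dA2/dt   = Q C - (Q/V2) A2

  with C the nonnegative root of C + Rtot C/(Kss+C) = Ctot and
  kin = BM0 * kout so that the drug-free state (0, BM0, 0) is stationary.

All concentrations are nM, times days, clearances L/day, volumes L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dataset import DoseEvent
from .units import DEFAULT_MOLAR_CONSTANTS, dose_mg_to_nmol

__all__ = [
    "PKParameters",
    "TMDDParameters",
    "MicroConstants",
    "SimulationTrajectory",
    "linear_pk_profile",
    "qss_free_drug",
    "qss_complex_and_target",
    "tmdd_rhs",
    "simulate_tmdd",
    "kss_from_micro",
    "first_dose_suppression",
    "target_accumulation_profile",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment model: clearance CL, central volume V1,
    intercompartmental clearance Q, peripheral volume V2."""

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        _check_positive(CL=self.CL, V1=self.V1, Q=self.Q, V2=self.V2)


@dataclass(frozen=True)
class TMDDParameters:
    """QSS TMDD parameters.  CL_RC is the elimination clearance of the
    drug-target complex (tied to CL during estimation); BM0 the baseline
    free-target concentration (nM); kout its first-order turnover rate
    (1/day); Kss the quasi-steady-state constant (nM)."""

    CL: float
    V1: float
    Q: float
    V2: float
    CL_RC: float
    BM0: float
    kout: float
    Kss: float

    def __post_init__(self) -> None:
        _check_positive(
            CL=self.CL, V1=self.V1, Q=self.Q, V2=self.V2,
            CL_RC=self.CL_RC, BM0=self.BM0, kout=self.kout, Kss=self.Kss,
        )

    @property
    def kin(self) -> float:
        """Zero-order target production rate, nM/day (= BM0 * kout)."""
        return self.BM0 * self.kout

    @property
    def pk(self) -> PKParameters:
        return PKParameters(self.CL, self.V1, self.Q, self.V2)


@dataclass(frozen=True)
class MicroConstants:
    """Binding micro-constants: association kon (1/nM/day), dissociation
    koff (1/day), complex internalisation/elimination kint (1/day)."""

    kon: float
    koff: float
    kint: float

    def __post_init__(self) -> None:
        if not self.kon > 0:
            raise ValueError(f"kon must be > 0, got {self.kon}")
        if self.koff < 0 or self.kint < 0:
            raise ValueError("koff and kint must be >= 0")


def kss_from_micro(m: MicroConstants) -> float:
    """Quasi-steady-state constant Kss = (kint + koff)/kon, nM."""
    return (m.kint + m.koff) / m.kon


@dataclass(frozen=True)
class SimulationTrajectory:
    """Time course of all five concentration series (nM)."""

    times: np.ndarray
    Ctot: np.ndarray  # total drug, central
    Rtot: np.ndarray  # total target
    C: np.ndarray  # free drug
    R: np.ndarray  # free target
    RC: np.ndarray  # complex

    def to_frame(self):
        """Tidy DataFrame (time, analyte, value, units)."""
        import pandas as pd

        frames = []
        for name, series in (
            ("total_drug", self.Ctot), ("total_target", self.Rtot),
            ("free_drug", self.C), ("free_target", self.R), ("complex", self.RC),
        ):
            frames.append(pd.DataFrame(
                {"time": self.times, "analyte": name, "value": series, "units": "nM"}
            ))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# linear two-compartment model, closed form


def _two_compartment_macro(p: PKParameters) -> tuple[float, float, float, float]:
    """Hybrid rate constants (alpha, beta) and central partition fractions
    (A, B) of the unit-bolus impulse response C(t) = (A e^-at + B e^-bt)/V1."""
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # guard degenerate limits: repeated root (measure zero) and an
    # underflowed slow eigenvalue at extreme parameter excursions
    if alpha == beta:
        alpha *= 1.0 + 1e-9
    beta = max(beta, alpha * 1e-15)
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    return alpha, beta, A, B


def linear_pk_profile(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    mw_drug: float = DEFAULT_MOLAR_CONSTANTS.mw_drug,
) -> np.ndarray:
    """Central-compartment total drug concentration (nM) at ``times``.

    Exact bi-exponential solution; infusion doses (mg) enter by
    superposition of constant-rate segments.  Times before the first dose
    return 0.
    """
    t = np.asarray(times, dtype=float)
    alpha, beta, A, B = _two_compartment_macro(params)
    conc = np.zeros_like(t)
    for d in doses:
        if d.amount == 0:
            continue
        rate = dose_mg_to_nmol(d.amount, mw_drug) / d.duration  # nmol/day
        for lam, frac in ((alpha, A), (beta, B)):
            # response of one exponential mode to a constant-rate infusion
            tau = np.clip(t - d.time, 0.0, None)  # time since infusion start
            dur = np.minimum(tau, d.duration)
            active = tau > 0
            contrib = np.zeros_like(t)
            contrib[active] = (
                rate * frac / (lam * params.V1)
                * (1.0 - np.exp(-lam * dur[active]))
                * np.exp(-lam * (tau[active] - dur[active]))
            )
            conc += contrib
    return conc


# ---------------------------------------------------------------------------
# QSS algebra


def _qss_free_scalar(ctot: float, rtot: float, kss: float) -> float:
    b = ctot - rtot - kss
    disc = math.sqrt(b * b + 4.0 * kss * ctot)
    if b >= 0.0:
        return 0.5 * (b + disc)
    # cancellation-safe branch for Ctot < Rtot + Kss
    return 2.0 * kss * ctot / (disc - b) if disc - b > 0 else 0.0


def qss_free_drug(Ctot, Rtot, Kss):
    """Free drug concentration C (nM): the nonnegative root of the QSS
    quadratic C^2 + (Rtot + Kss - Ctot) C - Kss Ctot = 0, computed in a
    cancellation-safe form.  Accepts scalars or arrays."""
    if np.any(np.asarray(Ctot) < 0) or np.any(np.asarray(Rtot) < 0):
        raise ValueError("Ctot and Rtot must be >= 0")
    if not np.all(np.asarray(Kss) > 0):
        raise ValueError("Kss must be > 0")
    if np.isscalar(Ctot) and np.isscalar(Rtot) and np.isscalar(Kss):
        return _qss_free_scalar(float(Ctot), float(Rtot), float(Kss))
    Ctot, Rtot, Kss = np.broadcast_arrays(
        np.asarray(Ctot, float), np.asarray(Rtot, float), np.asarray(Kss, float)
    )
    b = Ctot - Rtot - Kss
    disc = np.sqrt(b * b + 4.0 * Kss * Ctot)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe = np.where(disc - b > 0, 2.0 * Kss * Ctot / (disc - b), 0.0)
    return np.where(b >= 0, 0.5 * (b + disc), safe)


def qss_complex_and_target(Ctot, Rtot, Kss):
    """Complex RC = Rtot C/(Kss+C) and free target R = Rtot - RC (nM)."""
    C = qss_free_drug(Ctot, Rtot, Kss)
    RC = Rtot * C / (Kss + C)
    R = Rtot - RC
    return RC, R


# ---------------------------------------------------------------------------
# QSS TMDD dynamics


def tmdd_rhs(
    state: Sequence[float],
    t: float,
    params: TMDDParameters,
    infusion_rate: float,
) -> np.ndarray:
    """Time derivative of (Ctot [nM], Rtot [nM], A2 [nmol]).

    ``infusion_rate`` is the drug input in nmol/day (constant over a
    segment; dose discontinuities are handled by the integrator driver).
    """
    ctot, rtot, a2 = state
    p = params
    C = _qss_free_scalar(max(ctot, 0.0), max(rtot, 0.0), p.Kss)
    occ = C / (p.Kss + C)  # bound fraction of target: RC = Rtot * occ
    dctot = (
        infusion_rate / p.V1
        - (p.CL / p.V1 + p.Q / p.V1) * C
        - (p.CL_RC / p.V1) * rtot * occ
        + (p.Q / p.V2) * a2 / p.V1
    )
    drtot = p.kin - p.kout * rtot - (p.CL_RC / p.V1 - p.kout) * rtot * occ
    da2 = p.Q * C - (p.Q / p.V2) * a2
    return np.array([dctot, drtot, da2])


def _dose_segments(doses: Sequence[DoseEvent], t_end: float) -> list[tuple[float, float, float]]:
    """Piecewise-constant infusion schedule covering [0, t_end]: segments
    (start, stop, rate) with the summed mg/day rate of all active
    infusions (overlaps add)."""
    edges = {0.0, t_end}
    for d in doses:
        edges.add(d.time)
        edges.add(min(d.end, t_end) if d.time < t_end else t_end)
    cuts = sorted(e for e in edges if 0.0 <= e <= t_end)
    segments = []
    for a, b in zip(cuts, cuts[1:]):
        if b <= a:
            continue
        mid = 0.5 * (a + b)
        rate = sum(d.rate for d in doses if d.time <= mid < d.end)
        segments.append((a, b, rate))
    return segments


def simulate_tmdd(
    params: TMDDParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    mw_drug: float = DEFAULT_MOLAR_CONSTANTS.mw_drug,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    engine: str = "fast",
) -> SimulationTrajectory:
    """Integrate the QSS TMDD system over a dosing regimen.

    Starts from the drug-free stationary state (Ctot=0, Rtot=BM0, A2=0);
    integration is restarted at every infusion start/stop so the solver
    never steps across a discontinuity in the input rate.  ``engine``
    selects the compiled Dormand-Prince integrator (default) or the
    generic scipy LSODA driver ("scipy"), kept as an independent
    cross-check.
    """
    t_req = np.asarray(times, dtype=float)
    if t_req.ndim != 1 or np.any(np.diff(t_req) < 0):
        raise ValueError("times must be a 1-D non-decreasing array")
    if np.any(t_req < 0):
        raise ValueError("times must be >= 0")
    t_end = float(t_req[-1]) if len(t_req) else 0.0

    segments = _dose_segments(doses, t_end)

    if engine == "fast":
        from ._fastsim import integrate_qss

        edges = np.array([0.0] + [b for _, b, _ in segments]) if segments \
            else np.array([0.0, max(t_end, 0.0)])
        rates = np.array([
            dose_mg_to_nmol(r, mw_drug) for _, _, r in segments
        ]) if segments else np.zeros(1)
        if edges[-1] < t_end:
            edges = np.append(edges, t_end)
            rates = np.append(rates, 0.0)
        p = (params.CL, params.V1, params.Q, params.V2, params.CL_RC,
             params.kin, params.kout, params.Kss)
        out = integrate_qss(
            p, edges, rates, t_req, np.array([0.0, params.BM0, 0.0]),
            rtol=rtol, atol=atol,
        )
        ctot = np.clip(out[0], 0.0, None)
        rtot = np.clip(out[1], 0.0, None)
        C = qss_free_drug(ctot, rtot, params.Kss)
        RC, R = qss_complex_and_target(ctot, rtot, params.Kss)
        return SimulationTrajectory(
            times=t_req, Ctot=ctot, Rtot=rtot, C=np.asarray(C), R=R, RC=RC
        )

    y = np.array([0.0, params.BM0, 0.0])
    out = np.empty((3, len(t_req)))
    out[:, t_req == 0.0] = y[:, None]

    for a, b, rate_mg in segments:
        mask = (t_req > a) & (t_req <= b)
        t_eval = np.unique(t_req[mask])
        rate_nmol = dose_mg_to_nmol(rate_mg, mw_drug) if rate_mg else 0.0
        sol = solve_ivp(
            lambda t, s: tmdd_rhs(s, t, params, rate_nmol),
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"TMDD integration failed in [{a}, {b}] at t={sol.t[-1] if len(sol.t) else a}: "
                f"{sol.message}"
            )
        if len(t_eval):
            lookup = {t: sol.y[:, i] for i, t in enumerate(sol.t)}
            for j in np.nonzero(mask)[0]:
                out[:, j] = lookup[t_req[j]]
        # carry state to segment end
        if sol.t[-1] != b:
            sol2 = solve_ivp(
                lambda t, s: tmdd_rhs(s, t, params, rate_nmol),
                (sol.t[-1] if len(sol.t) else a, b),
                sol.y[:, -1] if len(sol.t) else y,
                method="LSODA", rtol=rtol, atol=atol,
            )
            y = sol2.y[:, -1]
        else:
            y = sol.y[:, -1]

    ctot = np.clip(out[0], 0.0, None)
    rtot = np.clip(out[1], 0.0, None)
    C = qss_free_drug(ctot, rtot, params.Kss)
    RC, R = qss_complex_and_target(ctot, rtot, params.Kss)
    return SimulationTrajectory(times=t_req, Ctot=ctot, Rtot=rtot, C=np.asarray(C), R=R, RC=RC)


def first_dose_suppression(
    params: TMDDParameters,
    dose_mg: float,
    infusion_duration: float,
    mw_drug: float = DEFAULT_MOLAR_CONSTANTS.mw_drug,
) -> float:
    """Percent drop in free target at the end of the first infusion,
    100 * (1 - R(t_inf)/BM0), simulated from baseline."""
    if dose_mg == 0:
        return 0.0
    dose = DoseEvent(time=0.0, amount=dose_mg, duration=infusion_duration)
    traj = simulate_tmdd(params, [dose], [0.0, infusion_duration], mw_drug=mw_drug)
    return 100.0 * (1.0 - traj.R[-1] / params.BM0)


def suppression_at_time(
    params: TMDDParameters,
    doses: Sequence[DoseEvent],
    time: float,
    mw_drug: float = DEFAULT_MOLAR_CONSTANTS.mw_drug,
) -> float:
    """Percent drop in free target relative to baseline at an arbitrary
    time under an arbitrary regimen (generic suppression query)."""
    traj = simulate_tmdd(params, doses, [0.0, time], mw_drug=mw_drug)
    return 100.0 * (1.0 - traj.R[-1] / params.BM0)


def target_accumulation_asymptote(params: TMDDParameters, C: float) -> float:
    """Total-target steady state under sustained constant free-drug
    concentration C: setting dRtot/dt = 0 gives
    Rtot_ss = kin / (kout (1-b) + (CL_RC/V1) b) with b = C/(Kss+C)."""
    b = C / (params.Kss + C)
    return params.kin / (params.kout * (1.0 - b) + (params.CL_RC / params.V1) * b)


def target_accumulation_profile(
    params: TMDDParameters,
    doses: Sequence[DoseEvent],
    horizon: float,
    n_points: int = 400,
    mw_drug: float = DEFAULT_MOLAR_CONSTANTS.mw_drug,
) -> tuple[SimulationTrajectory, float]:
    """Total-target trajectory over ``horizon`` days plus its asymptote at
    the average steady-state free-drug concentration of the regimen."""
    times = np.linspace(0.0, horizon, n_points)
    traj = simulate_tmdd(params, doses, times, mw_drug=mw_drug)
    if doses:
        interval = _mean_dose_interval(doses)
        css_avg_tot = dose_mg_to_nmol(doses[-1].amount, mw_drug) / (params.CL * interval)
        c_avg = _qss_free_scalar(css_avg_tot, float(traj.Rtot[-1]), params.Kss)
    else:
        c_avg = 0.0
    return traj, target_accumulation_asymptote(params, c_avg)


def _mean_dose_interval(doses: Sequence[DoseEvent]) -> float:
    starts = [d.time for d in doses]
    if len(starts) < 2:
        return 14.0
    return float(np.mean(np.diff(starts)))
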