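"""Compiled integrator for the QSS TMDD system.

A Dormand-Prince RK5(4) integrator specialised to the 3-state QSS
system, jit-compiled with numba.  The system is non-stiff on the
day scale of antibody kinetics (all rate constants well below 1/day
outside the infusion windows, whose fast dynamics are smooth), so an
explicit adaptive method with tight tolerances is both accurate and
orders of magnitude faster than generic callback-based solvers.
Integration proceeds segment by segment between infusion on/off
boundaries and lands exactly on every requested output time.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_qss"]


@njit(cache=True, fastmath=False)
def _qss_free(ctot: float, rtot: float, kss: float) -> float:
    b = ctot - rtot - kss
    disc = np.sqrt(b * b + 4.0 * kss * ctot)
    if b >= 0.0:
        return 0.5 * (b + disc)
    denom = disc - b
    if denom > 0.0:
        return 2.0 * kss * ctot / denom
    return 0.0


@njit(cache=True, fastmath=False)
def _rhs(y, p, rate):
    # p = (CL, V1, Q, V2, CL_RC, kin, kout, Kss); rate in nmol/day
    ctot = y[0] if y[0] > 0.0 else 0.0
    rtot = y[1] if y[1] > 0.0 else 0.0
    a2 = y[2]
    C = _qss_free(ctot, rtot, p[7])
    occ = C / (p[7] + C)
    d = np.empty(3)
    d[0] = rate / p[1] - (p[0] / p[1] + p[2] / p[1]) * C \
        - (p[4] / p[1]) * rtot * occ + (p[2] / p[3]) * a2 / p[1]
    d[1] = p[5] - p[6] * rtot - (p[4] / p[1] - p[6]) * rtot * occ
    d[2] = p[2] * C - (p[2] / p[3]) * a2
    return d


# Dormand-Prince coefficients
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0, 0.0],
    [44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0, 0.0, 0.0, 0.0],
    [19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0, 0.0, 0.0],
    [9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0,
     -5103.0 / 18656.0, 0.0],
])
_B5 = np.array([35.0 / 384.0, 0.0, 500.0 / 1113.0, 125.0 / 192.0,
                -2187.0 / 6784.0, 11.0 / 84.0, 0.0])
_B4 = np.array([5179.0 / 57600.0, 0.0, 7571.0 / 16695.0, 393.0 / 640.0,
                -92097.0 / 339200.0, 187.0 / 2100.0, 1.0 / 40.0])
_C = np.array([0.0, 0.2, 0.3, 0.8, 8.0 / 9.0, 1.0, 1.0])


@njit(cache=True, fastmath=False)
def _integrate_segment(y, t0, t1, p, rate, t_out, out, out_pos, rtol, atol):
    """Advance y from t0 to t1, writing states at the requested output
    times that fall in (t0, t1].  Returns the new out_pos."""
    n_out = len(t_out)
    t = t0
    span = t1 - t0
    h = span * 0.1 if span * 0.1 < 1.0 else 1.0
    if h <= 0.0:
        return out_pos
    k = np.empty((7, 3))
    max_steps = 20000
    done = False
    for _ in range(max_steps):
        if t >= t1:
            done = True
            break
        # do not step past the segment end or the next output time
        h_max = t1 - t
        if out_pos < n_out and t_out[out_pos] <= t1 and t_out[out_pos] - t < h_max:
            h_max = t_out[out_pos] - t
        if h > h_max:
            h = h_max
        if h < 1e-14:
            h = 1e-14
        # RK stages
        k[0] = _rhs(y, p, rate)
        for i in range(1, 7):
            yi = y.copy()
            for j in range(i if i < 6 else 6):
                if i < 6:
                    aij = _A[i, j]
                else:
                    aij = _B5[j]
                yi = yi + h * aij * k[j]
            k[i] = _rhs(yi, p, rate)
        y5 = y.copy()
        y4 = y.copy()
        for j in range(7):
            y5 = y5 + h * _B5[j] * k[j]
            y4 = y4 + h * _B4[j] * k[j]
        # error control
        err = 0.0
        for m in range(3):
            sc = atol + rtol * max(abs(y[m]), abs(y5[m]))
            e = (y5[m] - y4[m]) / sc
            err += e * e
        err = np.sqrt(err / 3.0)
        if err <= 1.0:
            t_new = t + h
            y = y5
            t = t_new
            while out_pos < n_out and t_out[out_pos] <= t + 1e-12 and t_out[out_pos] <= t1:
                out[:, out_pos] = y
                out_pos += 1
            factor = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
            h = h * factor
        else:
            h = h * max(0.2, 0.9 * err ** -0.2)
    if not (done or t >= t1):
        return -out_pos - 1  # step budget exhausted: signal failure
    return out_pos


@njit(cache=True, fastmath=False)
def _drive(y0, edges, rates, p, t_out, rtol, atol):
    # every segment end is guaranteed to be an output time (the caller
    # augments t_out with the edges), so the state carries across
    # segments through the output array
    out = np.empty((3, len(t_out)))
    y = y0.copy()
    out_pos = 0
    while out_pos < len(t_out) and t_out[out_pos] <= edges[0] + 1e-15:
        out[:, out_pos] = y
        out_pos += 1
    for s in range(len(rates)):
        out_pos = _integrate_segment(y, edges[s], edges[s + 1], p, rates[s],
                                     t_out, out, out_pos, rtol, atol)
        if out_pos < 0:  # step budget exhausted inside this segment
            return out, edges[s]
        y = out[:, out_pos - 1].copy()
    return out, np.inf


def integrate_qss(params_tuple, edges, rates, t_out, y0, rtol=1e-8, atol=1e-10):
    """Integrate the QSS system over a piecewise-constant infusion
    schedule.  ``edges`` (len n+1) and ``rates`` (len n, nmol/day) define
    the segments; ``t_out`` must be sorted and covered by the edges.
    Returns a (3, len(t_out)) state array."""
    # sentinel outputs at every segment end carry the state across
    # segments; they are stripped before returning
    t_out = np.asarray(t_out, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.float64)
    rates = np.asarray(rates, dtype=np.float64)
    aug = np.unique(np.concatenate((t_out, edges)))
    out, failed_at = _drive(np.asarray(y0, dtype=np.float64), edges, rates,
                            np.asarray(params_tuple, dtype=np.float64), aug,
                            rtol, atol)
    if np.isfinite(failed_at):
        raise RuntimeError(
            f"integration step budget exhausted after t={failed_at} "
            "(system too stiff at these parameters)"
        )
    idx = np.searchsorted(aug, t_out)
    return out[:, idx]
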