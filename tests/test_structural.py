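import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from bevtmdd.dataset import DoseEvent
from bevtmdd.structural import (
    MicroConstants,
    PKParameters,
    TMDDParameters,
    first_dose_suppression,
    kss_from_micro,
    linear_pk_profile,
    qss_complex_and_target,
    qss_free_drug,
    simulate_tmdd,
    suppression_at_time,
    target_accumulation_asymptote,
    target_accumulation_profile,
    tmdd_rhs,
)
from bevtmdd.units import dose_mg_to_nmol

INF_90MIN = 90.0 / 1440.0


class TestLinearPK:
    def test_empty_dose_list_gives_zero_profile(self):
        p = PKParameters(0.17, 3.14, 0.36, 2.63)
        t = np.linspace(0, 30, 50)
        assert np.all(linear_pk_profile(p, [], t) == 0.0)

    def test_times_before_first_dose_are_zero(self):
        p = PKParameters(0.17, 3.14, 0.36, 2.63)
        c = linear_pk_profile(p, [DoseEvent(5.0, 350.0, INF_90MIN)], [0.0, 2.0, 6.0])
        assert c[0] == 0.0 and c[1] == 0.0 and c[2] > 0.0

    def test_one_compartment_limit_matches_closed_form(self):
        # with Q ~ 0 the model collapses to one compartment, where the
        # during-infusion solution is D/(CL T) (1 - exp(-CL/V1 t))
        CL, V1, T = 0.5, 3.0, 1.0
        p = PKParameters(CL, V1, 1e-10, 1.0)
        dose_mg = 149.0  # 1000 nmol at 149 kDa
        t = np.linspace(0.05, T, 7)
        c = linear_pk_profile(p, [DoseEvent(0.0, dose_mg, T)], t)
        d_nmol = dose_mg_to_nmol(dose_mg, 149_000.0)
        expected = d_nmol / (CL * T) * (1.0 - np.exp(-CL / V1 * t))
        assert c == pytest.approx(expected, rel=1e-6)

    def test_end_of_infusion_concentration_near_dose_over_v1(self):
        p = PKParameters(0.17, 3.14, 0.36, 2.63)
        c = linear_pk_profile(p, [DoseEvent(0.0, 350.0, INF_90MIN)], [INF_90MIN])
        assert c[0] == pytest.approx(
            dose_mg_to_nmol(350.0, 149_000.0) / p.V1, rel=0.03
        )

    def test_matches_numeric_ode_oracle(self):
        p = PKParameters(0.17, 3.14, 0.36, 2.63)
        doses = [DoseEvent(0.0, 350.0, INF_90MIN), DoseEvent(14.0, 350.0, INF_90MIN)]
        times = np.array([0.05, 1.0, 7.0, 13.9, 14.2, 20.0, 28.0])

        def rhs(t, y):
            rate = sum(
                dose_mg_to_nmol(d.amount, 149_000.0) / d.duration
                for d in doses if d.time <= t < d.end
            )
            c1 = y[0] / p.V1
            return [
                rate - p.CL * c1 - p.Q * c1 + (p.Q / p.V2) * y[1],
                p.Q * c1 - (p.Q / p.V2) * y[1],
            ]

        sol = solve_ivp(
            rhs, (0.0, 28.0), [0.0, 0.0], rtol=1e-10, atol=1e-12,
            t_eval=times, max_step=0.02,
        )
        assert linear_pk_profile(p, doses, times) == pytest.approx(
            sol.y[0] / p.V1, rel=1e-3
        )


class TestQssAlgebra:
    def test_no_target_free_equals_total(self):
        assert qss_free_drug(10.0, 0.0, 267.0) == pytest.approx(10.0)

    def test_no_drug_gives_zero(self):
        assert qss_free_drug(0.0, 0.0053, 267.0) == 0.0

    def test_matches_fixed_point_iteration(self):
        ctot, rtot, kss = 727.0, 0.0053, 267.0
        c = ctot
        for _ in range(60):
            c = ctot - rtot * c / (kss + c)
        assert qss_free_drug(ctot, rtot, kss) == pytest.approx(c, rel=1e-12)

    def test_half_saturation_splits_target_evenly(self):
        kss, rtot = 267.0, 5.0
        ctot = kss + rtot * kss / (kss + kss)  # chosen so C = Kss
        rc, r = qss_complex_and_target(ctot, rtot, kss)
        assert r == pytest.approx(rtot / 2.0, rel=1e-9)
        assert rc == pytest.approx(rtot / 2.0, rel=1e-9)

    def test_zero_target_gives_zero_complex(self):
        assert qss_complex_and_target(100.0, 0.0, 267.0) == (0.0, 0.0)

    def test_free_target_fraction_identity(self):
        ctot, rtot, kss = 727.0, 0.0053, 267.0
        c = qss_free_drug(ctot, rtot, kss)
        _, r = qss_complex_and_target(ctot, rtot, kss)
        assert r / rtot == pytest.approx(kss / (kss + c), rel=1e-10)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            qss_free_drug(-1.0, 1.0, 267.0)
        with pytest.raises(ValueError):
            qss_free_drug(1.0, 1.0, 0.0)

    @given(
        ctot=st.floats(min_value=1e-6, max_value=1e5),
        rtot=st.floats(min_value=1e-9, max_value=1e3),
        kss=st.floats(min_value=1e-3, max_value=1e4),
    )
    @settings(max_examples=150, deadline=None)
    def test_root_matches_bisection_oracle(self, ctot, rtot, kss):
        # mass balance f(C) = C + Rtot C/(Kss+C) - Ctot is monotone in C
        f = lambda c: c + rtot * c / (kss + c) - ctot
        root = brentq(f, 0.0, ctot, xtol=1e-15, rtol=1e-14)
        c = qss_free_drug(ctot, rtot, kss)
        assert c == pytest.approx(root, rel=1e-9, abs=1e-12)
        # conservation identity
        assert c + rtot * c / (kss + c) == pytest.approx(ctot, rel=1e-10)


class TestKssFromMicro:
    @pytest.mark.parametrize(
        "kon,koff,kint,expected",
        [(5.0, 10.0, 0.0, 2.0), (5.0, 10.0, 2.0, 2.4), (1.0, 0.0, 0.0, 0.0)],
    )
    def test_values(self, kon, koff, kint, expected):
        assert kss_from_micro(MicroConstants(kon, koff, kint)) == pytest.approx(expected)

    def test_nonpositive_kon_rejected(self):
        with pytest.raises(ValueError):
            MicroConstants(0.0, 1.0, 1.0)


class TestTmddRhs:
    def test_drug_free_baseline_is_stationary(self, tmdd_typical):
        d = tmdd_rhs([0.0, tmdd_typical.BM0, 0.0], 0.0, tmdd_typical, 0.0)
        assert np.allclose(d, 0.0, atol=1e-14)

    def test_reduces_to_linear_pk_as_target_vanishes(self, tmdd_typical):
        import dataclasses

        p = dataclasses.replace(tmdd_typical, BM0=1e-12)
        state = [500.0, 1e-12, 800.0]
        d = tmdd_rhs(state, 0.0, p, 0.0)
        c1 = state[0]
        expected = [
            -(p.CL / p.V1 + p.Q / p.V1) * c1 + (p.Q / p.V2) * state[2] / p.V1,
            pytest.approx(0.0, abs=1e-10),
            p.Q * c1 - (p.Q / p.V2) * state[2],
        ]
        assert d[0] == pytest.approx(expected[0], rel=1e-9)
        assert d[2] == pytest.approx(expected[2], rel=1e-12)

    def test_target_derivative_matches_finite_difference(self, tmdd_typical):
        # independent check of dRtot/dt against a finite difference of the
        # integrated trajectory
        doses = [DoseEvent(0.0, 350.0, INF_90MIN)]
        t0, h = 3.0, 1e-4
        traj = simulate_tmdd(
            tmdd_typical, doses, [t0 - h, t0, t0 + h],
            rtol=1e-11, atol=1e-13, engine="scipy",
        )
        fd = (traj.Rtot[2] - traj.Rtot[0]) / (2 * h)
        # dRtot/dt depends only on (Ctot, Rtot), not on the peripheral state
        state = [traj.Ctot[1], traj.Rtot[1], 0.0]
        d = tmdd_rhs(state, t0, tmdd_typical, 0.0)
        assert d[1] == pytest.approx(fd, rel=1e-5)


class TestSimulateTmdd:
    def test_zero_dose_regimen_is_stationary(self, tmdd_typical):
        t = np.linspace(0.0, 100.0, 40)
        traj = simulate_tmdd(tmdd_typical, [], t)
        assert np.max(np.abs(traj.Rtot - tmdd_typical.BM0)) / tmdd_typical.BM0 < 1e-8
        assert np.all(traj.Ctot == 0.0)

    def test_reduction_to_linear_pk_at_vanishing_target(self):
        import dataclasses

        p = TMDDParameters(CL=0.18, V1=3.23, Q=1.38, V2=3.1, CL_RC=0.18,
                           BM0=1e-9, kout=0.401, Kss=267.0)
        doses = [DoseEvent(0.0, 350.0, INF_90MIN)]
        t = np.linspace(0.05, 28.0, 25)
        traj = simulate_tmdd(p, doses, t)
        linear = linear_pk_profile(p.pk, doses, t)
        assert np.max(np.abs(traj.Ctot - linear) / linear) < 1e-3

    def test_conservation_identities_along_trajectory(self, tmdd_typical):
        doses = [DoseEvent(0.0, 350.0, INF_90MIN), DoseEvent(14.0, 350.0, INF_90MIN)]
        t = np.linspace(0.0, 28.0, 60)
        traj = simulate_tmdd(tmdd_typical, doses, t)
        assert traj.C + traj.RC == pytest.approx(traj.Ctot, rel=1e-7, abs=1e-12)
        assert traj.R + traj.RC == pytest.approx(traj.Rtot, rel=1e-7, abs=1e-12)
        for series in (traj.Ctot, traj.Rtot, traj.C, traj.R, traj.RC):
            assert np.all(series >= 0.0)

    def test_fast_engine_agrees_with_scipy_engine(self, tmdd_typical):
        doses = [DoseEvent(0.0, 350.0, INF_90MIN), DoseEvent(14.0, 525.0, 1 / 24)]
        t = np.array([0.0, 0.0625, 1.0, 5.0, 13.9, 14.1, 20.0, 28.0])
        fast = simulate_tmdd(tmdd_typical, doses, t, rtol=1e-9, atol=1e-11)
        ref = simulate_tmdd(tmdd_typical, doses, t, rtol=1e-10, atol=1e-12,
                            engine="scipy")
        assert fast.Ctot[1:] == pytest.approx(ref.Ctot[1:], rel=1e-6)
        assert fast.Rtot == pytest.approx(ref.Rtot, rel=1e-6)

    def test_decreasing_times_rejected(self, tmdd_typical):
        with pytest.raises(ValueError):
            simulate_tmdd(tmdd_typical, [], [1.0, 0.5])


class TestSuppression:
    def test_zero_dose_gives_zero_suppression(self, tmdd_typical):
        assert first_dose_suppression(tmdd_typical, 0.0, INF_90MIN) == 0.0

    def test_reported_suppression_for_both_study_doses(self, tmdd_typical):
        # 5 mg/kg and 7.5 mg/kg for a 70 kg patient, 90-min infusion
        assert round(first_dose_suppression(tmdd_typical, 350.0, INF_90MIN)) == 73
        assert round(first_dose_suppression(tmdd_typical, 525.0, INF_90MIN)) == 80

    def test_agrees_with_analytic_shortcut(self, tmdd_typical):
        # at end of a short infusion C ~ dose/V1 and the drop is
        # 100 C/(Kss + C)
        for dose in (350.0, 525.0):
            c_end = dose_mg_to_nmol(dose, 149_000.0) / tmdd_typical.V1
            shortcut = 100.0 * c_end / (tmdd_typical.Kss + c_end)
            simulated = first_dose_suppression(tmdd_typical, dose, INF_90MIN)
            assert abs(simulated - shortcut) < 1.0  # one percentage point

    def test_monotone_in_dose_and_kss(self, tmdd_typical):
        import dataclasses

        drops = [first_dose_suppression(tmdd_typical, d, INF_90MIN)
                 for d in (100.0, 250.0, 400.0, 600.0)]
        assert all(b > a for a, b in zip(drops, drops[1:]))
        by_kss = [
            first_dose_suppression(
                dataclasses.replace(tmdd_typical, Kss=k), 350.0, INF_90MIN
            )
            for k in (100.0, 267.0, 600.0)
        ]
        assert all(b < a for a, b in zip(by_kss, by_kss[1:]))

    def test_generic_suppression_query(self, tmdd_typical):
        doses = [DoseEvent(0.0, 350.0, INF_90MIN)]
        assert suppression_at_time(tmdd_typical, doses, INF_90MIN) == pytest.approx(
            first_dose_suppression(tmdd_typical, 350.0, INF_90MIN), rel=1e-6
        )


class TestTargetAccumulation:
    def test_no_drug_asymptote_is_baseline(self, tmdd_typical):
        assert target_accumulation_asymptote(tmdd_typical, 0.0) == pytest.approx(
            tmdd_typical.BM0
        )

    def test_asymptote_is_baseline_when_complex_clearance_matches_kout(self):
        # CL_RC/V1 = kout removes the binding term from the total-target
        # balance
        p = TMDDParameters(CL=0.18, V1=3.0, Q=1.38, V2=3.1, CL_RC=0.3 * 3.0,
                           BM0=0.0053, kout=0.3, Kss=267.0)
        assert target_accumulation_asymptote(p, 500.0) == pytest.approx(p.BM0)

    def test_constant_exposure_asymptote_matches_algebra(self, tmdd_typical):
        # steady state of the total-target balance at constant C = 932 nM
        p = tmdd_typical
        c = 932.0
        b = c / (p.Kss + c)
        expected = p.kin / (p.kout * (1 - b) + (p.CL_RC / p.V1) * b)
        assert target_accumulation_asymptote(p, c) == pytest.approx(expected)
        assert expected / p.BM0 == pytest.approx(3.0, abs=0.1)

    def test_total_target_rises_toward_asymptote(self, tmdd_typical):
        doses = [DoseEvent(14.0 * c, 350.0, INF_90MIN) for c in range(10)]
        traj, asymptote = target_accumulation_profile(tmdd_typical, doses, 140.0)
        # trough-to-trough the total target is non-decreasing
        troughs = [traj.Rtot[np.argmin(np.abs(traj.times - 14.0 * c))]
                   for c in range(1, 10)]
        assert all(b >= a * 0.999 for a, b in zip(troughs, troughs[1:]))
        assert troughs[-1] < asymptote * 1.05
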