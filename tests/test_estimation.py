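import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import bevtmdd.estimation as est
from bevtmdd.dataset import (
    Analyte,
    DoseEvent,
    Observation,
    PatientCovariates,
    Sex,
    StudyDataset,
    Subject,
)
from bevtmdd.estimation import (
    ObjectiveSettings,
    chi2_quantile,
    empirical_bayes,
    fit,
    lrt,
    ofv,
    shrinkage,
    standard_errors,
    subject_joint_neg2ll,
    subject_laplace_contribution,
)
from bevtmdd.population import (
    ErrorModel,
    PopulationModelSpec,
    ResidualErrorSpec,
    StructuralModel,
)

SETT = ObjectiveSettings()


def _loglinear_spec(sigma=0.3, omega=(0.2, 0.25, 0.3)):
    """TMDD-shaped spec whose (patched) predictions are log-linear in the
    random effects: log f = Z (log theta + eta) + const."""
    return PopulationModelSpec(
        structural=StructuralModel.QSS_TMDD,
        theta={"CL": 0.18, "V1": 3.23, "Q": 1.38, "V2": 3.1,
               "BM0": 0.0053, "kout": 0.401, "Kss": 267.0},
        omega2={"CL": omega[0] ** 2, "V1": omega[1] ** 2, "BM0": omega[2] ** 2},
        error={a: ResidualErrorSpec(ErrorModel.ADDITIVE_LOG, sigma)
               for a in (Analyte.TOTAL_DRUG, Analyte.FREE_TARGET)},
    )


def _subject(dv_values, analyte=Analyte.FREE_TARGET):
    obs = tuple(
        Observation(float(j), analyte, float(v), missing=False)
        for j, v in enumerate(dv_values, start=1)
    )
    return Subject(
        "L1", PatientCovariates(70.0, 60.0, Sex.M),
        (DoseEvent(0.0, 350.0, 0.0625),), obs,
    )


def _patch_loglinear(monkeypatch, Z, const):
    """Patch the structural prediction with f = exp(const + Z log(P)),
    P = (CL, V1, BM0): exactly linear in eta on the log scale."""

    def fake_predict(data, spec, params, settings):
        logp = np.log([params.CL, params.V1, params.BM0])
        return np.exp(const + Z @ logp)

    monkeypatch.setattr(est, "_predict_f", fake_predict)


class TestJointNeg2ll:
    def test_no_observations_reduces_to_prior(self, tmdd_spec):
        subject = Subject(
            "S", PatientCovariates(70.0, 60.0, Sex.M),
            (DoseEvent(0.0, 350.0, 0.0625),), (),
        )
        eta = {"CL": 0.1, "V1": -0.2, "BM0": 0.05}
        val = subject_joint_neg2ll(
            tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, subject, eta
        )
        expected = sum(
            math.log(2 * math.pi * tmdd_spec.omega2[p]) + eta[p] ** 2 / tmdd_spec.omega2[p]
            for p in ("CL", "V1", "BM0")
        )
        assert val == pytest.approx(expected, rel=1e-12)

    def test_matches_pencil_and_paper_gaussian(self, monkeypatch):
        # one observation, log f = log BM0 + eta: joint -2LL is the sum of
        # two Gaussian terms evaluated directly
        spec = _loglinear_spec(sigma=0.4, omega=(0.2, 0.25, 0.3))
        Z = np.array([[0.0, 0.0, 1.0]])
        _patch_loglinear(monkeypatch, Z, np.array([0.0]))
        subject = _subject([0.004])
        eta = {"BM0": 0.12}
        val = subject_joint_neg2ll(spec, spec.theta, spec.omega2, subject, eta)
        y = math.log(0.004 * 1.0 / 40_000.0)  # ng/L -> nM at the 40 kDa mass
        m = math.log(spec.theta["BM0"]) + 0.12
        expected = (
            math.log(2 * math.pi * 0.4**2) + (y - m) ** 2 / 0.4**2
            + math.log(2 * math.pi * 0.2**2)
            + math.log(2 * math.pi * 0.25**2)
            + math.log(2 * math.pi * 0.3**2) + 0.12**2 / 0.3**2
        )
        assert val == pytest.approx(expected, rel=1e-10)


class TestLaplaceOracle:
    def test_equals_closed_form_lmm_marginal(self, monkeypatch):
        # on models linear in eta with Gaussian error the Laplace formula
        # is exact: compare with the multivariate-normal marginal
        rng = np.random.default_rng(1234)
        for trial in range(8):
            n_obs = rng.integers(2, 7)
            sigma = float(rng.uniform(0.1, 0.5))
            omega = rng.uniform(0.1, 0.5, size=3)
            spec = _loglinear_spec(sigma=sigma, omega=tuple(omega))
            Z = rng.normal(0, 1, size=(n_obs, 3))
            const = rng.normal(0, 1, size=n_obs)
            _patch_loglinear(monkeypatch, Z, const)
            dv = np.exp(rng.normal(-5, 1, size=n_obs)) * 40_000.0  # ng/L
            subject = _subject(dv)

            contrib, eta_hat, _, ok = subject_laplace_contribution(
                spec, spec.theta, spec.omega2, subject, SETT
            )
            assert ok
            y = np.log(dv / 40_000.0)
            mean = const + Z @ np.log([spec.theta["CL"], spec.theta["V1"],
                                       spec.theta["BM0"]])
            cov = Z @ np.diag(omega**2) @ Z.T + sigma**2 * np.eye(n_obs)
            oracle = -2.0 * stats.multivariate_normal.logpdf(y, mean, cov)
            assert contrib == pytest.approx(oracle, rel=1e-6), f"trial {trial}"

    def test_real_model_baseline_subject_is_exact_lmm(self):
        # pre-dose free-target observations only: log R(0) = log BM0 + eta,
        # a genuine linear mixed model inside the real structural model
        spec = PopulationModelSpec(
            structural=StructuralModel.QSS_TMDD,
            theta={"CL": 0.18, "V1": 3.23, "Q": 1.38, "V2": 3.1,
                   "BM0": 0.0053, "kout": 0.401, "Kss": 267.0},
            omega2={"BM0": 0.33**2},
            error={a: ResidualErrorSpec(ErrorModel.ADDITIVE_LOG, 0.32)
                   for a in (Analyte.TOTAL_DRUG, Analyte.FREE_TARGET)},
        )
        dv = [180.0, 250.0, 199.0]
        obs = tuple(Observation(0.0, Analyte.FREE_TARGET, v) for v in dv)
        subject = Subject(
            "B", PatientCovariates(70.0, 60.0, Sex.M),
            (DoseEvent(1.0, 350.0, 0.0625),), obs,
        )
        contrib, _, _, ok = subject_laplace_contribution(
            spec, spec.theta, spec.omega2, subject, SETT
        )
        assert ok
        y = np.log(np.array(dv) / 40_000.0)
        mean = np.full(3, math.log(0.0053))
        cov = 0.33**2 * np.ones((3, 3)) + 0.32**2 * np.eye(3)
        oracle = -2.0 * stats.multivariate_normal.logpdf(y, mean, cov)
        assert contrib == pytest.approx(oracle, rel=1e-6)

    def test_vanishing_omega_recovers_fixed_effects_likelihood(self, monkeypatch):
        spec = _loglinear_spec(sigma=0.3, omega=(1e-5, 1e-5, 1e-5))
        Z = np.eye(3)
        _patch_loglinear(monkeypatch, Z, np.zeros(3))
        dv = np.array([0.2, 3.0, 0.006]) * 40_000.0
        subject = _subject(dv)
        contrib, eta_hat, _, _ = subject_laplace_contribution(
            spec, spec.theta, spec.omega2, subject, SETT
        )
        assert all(abs(v) < 1e-3 for v in eta_hat.values())
        y = np.log(dv / 40_000.0)
        mean = np.log([spec.theta["CL"], spec.theta["V1"], spec.theta["BM0"]])
        fixed = float(np.sum(np.log(2 * np.pi * 0.3**2) + (y - mean) ** 2 / 0.3**2))
        assert contrib == pytest.approx(fixed, rel=1e-4)

    def test_mirrored_subjects_contribute_equally(self, tmdd_spec):
        from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

        skeleton = generate_rich_cohort(1, 6, seed=5)
        ds, _ = simulate_observations(skeleton, tmdd_spec, seed=6)
        s = ds.subjects[0]
        twin = dataclasses.replace(s, id="twin")
        c1, e1, _, _ = subject_laplace_contribution(
            tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, s, SETT
        )
        c2, e2, _, _ = subject_laplace_contribution(
            tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, twin, SETT
        )
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert e1 == e2


@pytest.fixture(scope="module")
def small_dataset(tmdd_spec):
    from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

    skeleton = generate_rich_cohort(4, 6, seed=7)
    ds, _ = simulate_observations(skeleton, tmdd_spec, seed=8)
    return ds


class TestOfv:
    def test_additive_over_subject_partition(self, tmdd_spec, small_dataset):
        whole = ofv(tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, small_dataset)
        half1 = StudyDataset(small_dataset.subjects[:2])
        half2 = StudyDataset(small_dataset.subjects[2:])
        parts = sum(
            ofv(tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, d)
            for d in (half1, half2)
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_invariant_under_subject_permutation(self, tmdd_spec, small_dataset):
        permuted = StudyDataset(small_dataset.subjects[::-1])
        assert ofv(tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, permuted) == \
            pytest.approx(
                ofv(tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, small_dataset),
                rel=1e-12,
            )

    def test_duplicated_subject_doubles_contribution(self, tmdd_spec, small_dataset):
        s = small_dataset.subjects[0]
        single = ofv(tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, StudyDataset((s,)))
        doubled = ofv(
            tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2,
            StudyDataset((s, dataclasses.replace(s, id="copy"))),
        )
        assert doubled == pytest.approx(2 * single, rel=1e-12)


class TestFit:
    def test_noiseless_data_identify_theta(self):
        # omega ~ 0 and tiny sigma: the fixed effects must come back
        # almost exactly from sparse data
        from bevtmdd.population import allometric_relations
        from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

        quiet = PopulationModelSpec(
            structural=StructuralModel.LINEAR_PK,
            theta={"CL": 0.17, "V1": 3.14, "Q": 0.36, "V2": 2.63},
            omega2={"CL": 1e-10, "V1": 1e-10},
            error={Analyte.TOTAL_DRUG: ResidualErrorSpec(ErrorModel.PROPORTIONAL, 1e-4)},
            relations=tuple(allometric_relations(["CL", "V1", "Q", "V2"])),
        )
        skeleton = generate_rich_cohort(5, 7, seed=9)
        ds, _ = simulate_observations(skeleton, quiet, seed=10)
        ds = ds.with_analytes([Analyte.TOTAL_DRUG])
        init = quiet.with_theta({"CL": 0.25, "V1": 4.0, "Q": 0.5, "V2": 4.0})
        res = fit(init, ds, SETT,
                  fix={"omega2_CL", "omega2_V1", "sigma_TOTAL_DRUG"})
        for p, truth in quiet.theta.items():
            assert res.theta[p] == pytest.approx(truth, rel=1e-3), p

    def test_deterministic_under_subject_permutation(self, tmdd_spec):
        from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

        skeleton = generate_rich_cohort(3, 5, seed=11)
        ds, _ = simulate_observations(skeleton, tmdd_spec, seed=12)
        permuted = StudyDataset(ds.subjects[::-1])
        # no free outer parameters: fit reduces to EBE + OFV evaluation
        fix = set(tmdd_spec.theta) | {"omega2_CL", "omega2_V1", "omega2_BM0",
                                      "sigma_TOTAL_DRUG", "sigma_FREE_TARGET"}
        r1 = fit(tmdd_spec, ds, SETT, fix=fix)
        r2 = fit(tmdd_spec, permuted, SETT, fix=fix)
        assert r1.ofv == pytest.approx(r2.ofv, rel=1e-12)
        assert r1.etas == r2.etas


class TestEmpiricalBayes:
    def test_uninformative_subject_has_zero_mode(self, tmdd_spec):
        subject = Subject(
            "N", PatientCovariates(70.0, 60.0, Sex.M),
            (DoseEvent(0.0, 350.0, 0.0625),), (),
        )
        _, eta_hat, _, _ = subject_laplace_contribution(
            tmdd_spec, tmdd_spec.theta, tmdd_spec.omega2, subject, SETT
        )
        assert all(v == 0.0 for v in eta_hat.values())

    def test_conjugate_gaussian_posterior_mode(self, monkeypatch):
        # log-linear single-effect model: posterior mode has the known
        # shrinkage form (sum of standardised residual precisions)
        spec = _loglinear_spec(sigma=0.3, omega=(0.2, 0.25, 0.4))
        Z = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        _patch_loglinear(monkeypatch, Z, np.zeros(2))
        dv = np.array([0.008, 0.009]) * 40_000.0
        subject = _subject(dv)
        _, eta_hat, _, _ = subject_laplace_contribution(
            spec, spec.theta, spec.omega2, subject, SETT
        )
        y = np.log(dv / 40_000.0)
        resid = y - math.log(spec.theta["BM0"])
        expected = resid.sum() / 0.3**2 / (2 / 0.3**2 + 1 / 0.4**2)
        assert eta_hat["BM0"] == pytest.approx(expected, abs=1e-4)
        assert eta_hat["CL"] == pytest.approx(0.0, abs=1e-8)


class TestShrinkage:
    def test_all_zero_modes_give_full_shrinkage(self, tmdd_spec):
        subjects = tuple(
            Subject(f"U{i}", PatientCovariates(70.0, 60.0, Sex.M),
                    (DoseEvent(0.0, 350.0, 0.0625),), ())
            for i in range(4)
        )
        ds = StudyDataset(subjects)
        fix = set(tmdd_spec.theta) | {"omega2_CL", "omega2_V1", "omega2_BM0",
                                      "sigma_TOTAL_DRUG", "sigma_FREE_TARGET"}
        res = fit(tmdd_spec, ds, SETT, fix=fix)
        eta_shr, eps_shr = shrinkage(res, ds)
        assert all(v == pytest.approx(100.0) for v in eta_shr.values())

    def test_sparse_design_shrinks_more_than_rich(self, tmdd_spec):
        from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

        fix = set(tmdd_spec.theta) | {"omega2_CL", "omega2_V1", "omega2_BM0",
                                      "sigma_TOTAL_DRUG", "sigma_FREE_TARGET"}
        shr = {}
        for name, n_samples in (("rich", 8), ("sparse", 2)):
            skeleton = generate_rich_cohort(12, n_samples, seed=13)
            ds, _ = simulate_observations(skeleton, tmdd_spec, seed=14)
            res = fit(tmdd_spec, ds, SETT, fix=fix)
            eta_shr, eps_shr = shrinkage(res, ds)
            shr[name] = eta_shr
        assert shr["sparse"]["CL"] > shr["rich"]["CL"]
        assert shr["sparse"]["BM0"] > shr["rich"]["BM0"]


class TestStandardErrors:
    def test_quadratic_objective_recovers_known_hessian(self, monkeypatch, pk_spec):
        # stub the OFV with an exact quadratic: the covariance step must
        # return 2 H^-1 (central differences are exact on quadratics)
        from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

        skeleton = generate_rich_cohort(2, 4, seed=15)
        ds, _ = simulate_observations(skeleton, pk_spec, seed=16)
        ds = ds.with_analytes([Analyte.TOTAL_DRUG])
        res = fit(pk_spec, ds, SETT,
                  fix=set(pk_spec.theta) | {"omega2_CL", "omega2_V1",
                                            "sigma_TOTAL_DRUG"})
        res.param_index = ["CL", "V1", "Q", "V2", "omega2:CL", "omega2:V1",
                           "sigma:TOTAL_DRUG"]
        n = 7
        rng = np.random.default_rng(17)
        A = rng.normal(size=(n, n))
        H = A @ A.T + n * np.eye(n)
        x_hat = est._Packing(res.spec, set()).pack()

        def quad_ofv(spec, theta, omega2, dataset, settings, relations=None,
                     warm_etas=None):
            x = _pack_from(spec, theta, omega2)
            d = x - x_hat
            return 10.0 + 0.5 * d @ H @ d

        def _pack_from(spec, theta, omega2):
            vals = [math.log(theta[p]) for p in ("CL", "V1", "Q", "V2")]
            vals += [math.log(omega2[p]) for p in ("CL", "V1")]
            vals += [math.log(spec.error[Analyte.TOTAL_DRUG].sigma)]
            return np.array(vals)

        monkeypatch.setattr(est, "ofv", quad_ofv)
        cov, rse = standard_errors(res, ds, step=1e-3)
        assert cov == pytest.approx(2.0 * np.linalg.inv(H), rel=1e-4, abs=1e-8)
        for k, name in enumerate(res.param_index):
            assert rse[name] == pytest.approx(100.0 * math.sqrt(cov[k, k]), rel=1e-9)

    def test_indefinite_hessian_fails_covariance_step(self, monkeypatch, pk_spec):
        from bevtmdd.synthetic import generate_rich_cohort, simulate_observations

        skeleton = generate_rich_cohort(2, 4, seed=18)
        ds, _ = simulate_observations(skeleton, pk_spec, seed=19)
        ds = ds.with_analytes([Analyte.TOTAL_DRUG])
        res = fit(pk_spec, ds, SETT,
                  fix=set(pk_spec.theta) | {"omega2_CL", "omega2_V1",
                                            "sigma_TOTAL_DRUG"})
        res.param_index = ["CL"]
        monkeypatch.setattr(
            est, "ofv",
            lambda spec, theta, omega2, dataset, settings, relations=None,
            warm_etas=None: -(math.log(theta["CL"]) - math.log(0.17)) ** 2,
        )
        cov, rse = standard_errors(res, ds)
        assert cov is None and rse is None


class TestLikelihoodRatio:
    def test_forward_and_backward_thresholds(self):
        assert chi2_quantile(0.95, 1) == pytest.approx(3.84, abs=0.005)
        assert chi2_quantile(0.99, 1) == pytest.approx(6.64, abs=0.01)
        assert chi2_quantile(0.5, 1) == pytest.approx(0.455, abs=0.001)

    def test_lrt_p_value_matches_chi2_tail(self):
        assert lrt(110.0, 100.0, 1) == pytest.approx(stats.chi2.sf(10.0, 1))
        assert lrt(110.0, 100.0, 2) == pytest.approx(stats.chi2.sf(10.0, 2))

    def test_negative_delta_reports_one(self):
        assert lrt(100.0, 110.0, 1) == 1.0

    def test_quantile_round_trips_with_lrt(self):
        crit = chi2_quantile(0.95, 3)
        assert lrt(100.0 + crit, 100.0, 3) == pytest.approx(0.05)
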