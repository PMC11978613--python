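import dataclasses

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mdjoint.datagen import generate_dataset, recovery_config
from mdjoint.jointmodel import (
    CohortLikelihood,
    FitResult,
    JointParams,
    ParamTransform,
    cumulative_hazard,
    hazard,
    joint_wald_test,
    subject_loglik,
    wald_inference,
)


def _first_subject(cohort):
    cfg, subjects, visits, truth = cohort
    row = subjects.iloc[0]
    return row, visits[visits["id"] == row["id"]]


def _zero_alpha(params):
    return dataclasses.replace(
        params,
        alpha={k: 0.0 for k in params.markers},
        gamma={k: 0.0 for k in params.gamma},
    )


class TestHazard:
    def test_baseline_only_when_no_association(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = _zero_alpha(truth["params"])
        ages = np.array([52.0, 58.0, 64.0])
        expected = np.exp(design.hazard_design(ages) @ params.omega)
        for i in (0, 5):
            lam = hazard(ages, subjects.iloc[i], design, params, np.zeros(2))
            assert np.allclose(lam, expected)

    def test_log_hazard_affine_in_alpha(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = truth["params"]
        row = subjects.iloc[3]
        b = np.array([0.4, -0.2])
        age = 60.0
        lam0 = hazard(age, row, design, params, b)
        bumped = dataclasses.replace(
            params, alpha={**params.alpha, "d": params.alpha["d"] + 0.1}
        )
        lam1 = hazard(age, row, design, bumped, b)
        from mdjoint.jointmodel import _subject_mu

        mu_d = _subject_mu([age], row, design, params, b)[1, 0]
        assert np.log(lam1) - np.log(lam0) == pytest.approx(0.1 * mu_d, abs=1e-10)

    def test_hazard_monotone_in_dense_intercept(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = truth["params"]  # alpha_d > 0
        row = subjects.iloc[0]
        ages = np.linspace(row["entry_age"], row["entry_age"] + 7, 20)
        lo = hazard(ages, row, design, params, np.array([0.0, -0.5]))
        hi = hazard(ages, row, design, params, np.array([0.0, 0.5]))
        assert (hi > lo).all()

    def test_manual_linear_predictor_assembly(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = truth["params"]
        row = subjects.iloc[7]
        b = np.array([0.3, 0.1])
        from mdjoint.splines import covariate_row, fixed_effects_matrix

        for age in (51.0, 57.5, 63.0):
            eta = design.hazard_design([age])[0] @ params.omega
            w = covariate_row(row, design.survival_covariates)
            gnames = ["bmi_baseline", "hrt_previous", "hrt_current", "hrt_missing",
                      "fh_yes", "fh_missing"]
            eta += w @ np.array([params.gamma[g] for g in gnames])
            for j, k in enumerate(("nd", "d")):
                X = fixed_effects_matrix([age], row, design.specs[k], design.marker_basis)
                eta += params.alpha[k] * (X[0] @ params.beta[k] + b[j])
            assert hazard(age, row, design, params, b) == pytest.approx(np.exp(eta))


class TestCumulativeHazard:
    def test_constant_hazard_is_exact(self):
        cfg = recovery_config(
            n_subjects=2, alpha={"nd": 0, "d": 0, "bmi": 0},
            gamma={k: 0.0 for k in ("bmi_baseline", "hrt_previous", "hrt_current",
                                    "hrt_missing", "fh_yes", "fh_missing")},
            log_rate_55=float(np.log(0.02)), hazard_slope=0.0,
        )
        subjects, visits, truth = generate_dataset(cfg)
        design = cfg.design(("nd", "d"))
        row = subjects.iloc[0]
        for nodes in (1, 5, 30):
            lam = cumulative_hazard(50.0, 58.0, row, design, truth["params"],
                                    np.zeros(2), n_nodes=nodes)
            assert lam == pytest.approx(0.02 * 8.0, rel=1e-12)

    def test_quadrature_convergence_and_additivity(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = truth["params"]
        row = subjects.iloc[0]
        b = np.array([0.2, 0.4])
        l30 = cumulative_hazard(50.0, 60.0, row, design, params, b, n_nodes=30)
        l60 = cumulative_hazard(50.0, 60.0, row, design, params, b, n_nodes=60)
        assert abs(l30 - l60) < 1e-8
        l1 = cumulative_hazard(50.0, 54.0, row, design, params, b)
        l2 = cumulative_hazard(54.0, 60.0, row, design, params, b)
        assert l1 + l2 == pytest.approx(l30, abs=1e-10)
        assert cumulative_hazard(50.0, 50.0, row, design, params, b) == 0.0
        with pytest.raises(ValueError):
            cumulative_hazard(60.0, 50.0, row, design, params, b)


class TestSubjectLoglik:
    def test_degenerate_random_effects_give_closed_form(self, small_cohort):
        """As Sigma_b -> 0 the marginal likelihood collapses to the product of
        the visit densities at b = 0 times the survival factor."""
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        tiny = dataclasses.replace(
            truth["params"], Sigma_b=np.eye(2) * 1e-12
        )
        censored = subjects[subjects["event"] == 0].iloc[0]
        v = visits[visits["id"] == censored["id"]]
        ll = subject_loglik(censored, v, design, tiny, n_ghq=7)
        from mdjoint.splines import build_marker_design

        closed = -cumulative_hazard(
            censored["entry_age"], censored["exit_age"], censored, design, tiny,
            np.zeros(2), n_nodes=30,
        )
        resid = []
        for k in ("nd", "d"):
            y, X, _ = build_marker_design(v, censored, design.specs[k], design.marker_basis)
            resid.append(y - X @ tiny.beta[k])
        resid = np.array(resid)
        for j in range(resid.shape[1]):
            closed += multivariate_normal.logpdf(resid[:, j], cov=tiny.Sigma_eps)
        assert ll == pytest.approx(closed, abs=1e-5)

    def test_vectorized_equals_per_subject(self, trivariate_cohort):
        cfg, subjects, visits, truth = trivariate_cohort
        design = cfg.design(("nd", "d", "bmi"))
        params = truth["params"]
        cl = CohortLikelihood(subjects, visits, design, n_ghq=9, n_gl=30)
        vec = cl.loglik_by_subject(params)
        for i in range(0, 25, 5):
            row = subjects.iloc[i]
            v = visits[visits["id"] == row["id"]]
            assert vec[i] == pytest.approx(
                subject_loglik(row, v, design, params, n_ghq=9, n_gl=30), abs=1e-8
            )

    def test_quadrature_node_convergence(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = truth["params"]
        ll7 = CohortLikelihood(subjects, visits, design, n_ghq=7).loglik(params)
        ll15 = CohortLikelihood(subjects, visits, design, n_ghq=15).loglik(params)
        assert abs(ll7 - ll15) < 1e-4 * len(subjects) / 100

    def test_left_truncation_is_not_a_noop(self, small_cohort):
        cfg, subjects, visits, truth = small_cohort
        design = cfg.design(("nd", "d"))
        params = truth["params"]
        row, v = _first_subject(small_cohort)
        base = subject_loglik(row, v, design, params)
        shifted = row.copy()
        shifted["entry_age"] = row["entry_age"] - 3.0
        assert subject_loglik(shifted, v, design, params) != pytest.approx(base, abs=1e-6)
        # the marginal-truncation correction is a further, distinct quantity
        marg = subject_loglik(row, v, design, params, truncation="marginal")
        assert marg != pytest.approx(base, abs=1e-8)

    def test_missing_bmi_marginalizes_to_bivariate(self, trivariate_cohort):
        """With block-diagonal covariances, alpha_bmi = 0 and every BMI visit
        missing, the trivariate likelihood equals the bivariate one."""
        cfg, subjects, visits, truth = trivariate_cohort
        p3 = truth["params"]
        p3 = dataclasses.replace(p3, alpha={**p3.alpha, "bmi": 0.0})
        design3 = cfg.design(("nd", "d", "bmi"))
        row = subjects.iloc[0]
        v = visits[visits["id"] == row["id"]].copy()
        v["bmi"] = np.nan
        ll3 = subject_loglik(row, v, design3, p3, n_ghq=11)

        design2 = dataclasses.replace(
            cfg.design(("nd", "d")), survival_covariates=("hrt", "fh")
        )
        p2 = JointParams(
            markers=("nd", "d"),
            beta={k: p3.beta[k] for k in ("nd", "d")},
            Sigma_b=p3.Sigma_b[:2, :2],
            Sigma_eps=p3.Sigma_eps[:2, :2],
            omega=p3.omega,
            gamma=p3.gamma,
            alpha={k: p3.alpha[k] for k in ("nd", "d")},
        )
        ll2 = subject_loglik(row, v, design2, p2, n_ghq=11)
        assert ll3 == pytest.approx(ll2, abs=1e-6)


class TestJointParamsValidation:
    def test_invariants(self, small_cohort):
        cfg, *_ , truth = small_cohort
        params = truth["params"]
        with pytest.raises(ValueError, match="positive definite"):
            dataclasses.replace(params, Sigma_b=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="markers"):
            dataclasses.replace(params, markers=("nd",), beta={"nd": params.beta["nd"]},
                                alpha={"nd": 0.0})
        trivariate = recovery_config(n_subjects=2, survival_mode="trivariate").true_params()
        with pytest.raises(ValueError, match="BMI"):
            dataclasses.replace(trivariate, gamma={**trivariate.gamma, "bmi_baseline": 0.1})

    def test_transform_roundtrip(self, small_cohort):
        cfg, *_, truth = small_cohort
        tf = ParamTransform(cfg.design(("nd", "d")))
        theta = tf.pack(truth["params"])
        back = tf.unpack(theta)
        assert np.allclose(back.Sigma_b, truth["params"].Sigma_b)
        assert np.allclose(back.Sigma_eps, truth["params"].Sigma_eps)
        assert np.allclose(back.alpha_vec, truth["params"].alpha_vec)
        assert np.allclose(tf.pack(back), theta)


class TestWaldInference:
    def _dummy_fit(self, names, theta, vcov):
        return FitResult(
            model="test", param_names=names, theta=np.asarray(theta, dtype=float),
            free=np.ones(len(names), dtype=bool), loglik=0.0, converged=True,
            n_iter=1, grad_inf=0.0, vcov=np.asarray(vcov, dtype=float),
        )

    def test_null_estimate_gives_unit_hr(self):
        fit = self._dummy_fit(["alpha:nd"], [0.0], [[0.04]])
        rows = wald_inference(fit)
        assert rows[0]["HR"] == pytest.approx(1.0)
        assert rows[0]["p"] == pytest.approx(1.0)
        assert rows[0]["ci_low"] < 1.0 < rows[0]["ci_high"]

    def test_single_term_chi2_is_squared_z(self):
        fit = self._dummy_fit(["alpha:d"], [0.30], [[0.01]])
        res = joint_wald_test(fit, ["alpha:d"])
        assert res["chi2"] == pytest.approx((0.30 / 0.10) ** 2)
        assert res["df"] == 1

    def test_two_term_chi2_matches_manual_linear_algebra(self):
        theta = np.array([0.2, -0.1])
        V = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit = self._dummy_fit(["a", "b"], theta, V)
        res = joint_wald_test(fit, ["a", "b"])
        assert res["chi2"] == pytest.approx(theta @ np.linalg.inv(V) @ theta)
        assert res["df"] == 2
        bad = self._dummy_fit(["a", "b"], theta, np.zeros((2, 2)) * np.nan)
        with pytest.raises(ValueError):
            joint_wald_test(bad, ["a", "b"])
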