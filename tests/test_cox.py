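import numpy as np
import pandas as pd
import pytest

from mdjoint.coxmodels import (
    conditional_logistic_fit,
    cox_partial_loglik,
    expand_counting_process,
    fit_cox,
    nested_case_control,
    reverse_km_median_followup,
    tertile_cut,
)
from .conftest import make_subject, make_visits


def toy_rows(starts, stops, events, x):
    return pd.DataFrame(
        dict(id=[f"s{i}" for i in range(len(x))], age_start=starts, age_stop=stops,
             event_in_interval=events, sqrt_nd=x, sqrt_d=np.zeros(len(x)))
    )


class TestPartialLoglik:
    def test_uniform_risk_sets_at_null(self):
        rows = toy_rows([0, 0, 0], [2, 4, 6], [1, 1, 0], [0.0, 1.0, 1.0])
        assert cox_partial_loglik(rows, [0, 0]) == pytest.approx(-np.log(3) - np.log(2))

    def test_matches_hand_enumerated_risk_sets(self):
        rows = toy_rows([0, 0, 0], [2, 4, 6], [1, 1, 0], [0.0, 1.0, 1.0])
        b = 0.5
        expected = (0 - np.log(1 + 2 * np.exp(b))) + (b - np.log(2 * np.exp(b)))
        assert cox_partial_loglik(rows, [b, 0]) == pytest.approx(expected)

    def test_delayed_entry_shrinks_risk_sets(self):
        rows = toy_rows([0, 3, 3], [2, 4, 6], [1, 1, 0], [0.0, 1.0, 1.0])
        # first event sees only its own subject; second sees two
        assert cox_partial_loglik(rows, [0, 0]) == pytest.approx(-np.log(1) - np.log(2))

    def test_efron_tie_correction(self):
        # two tied events among three at risk, all eta = 0: Efron denominators
        # are 3 and 3 - (1/2)*2 = 2
        rows = toy_rows([0, 0, 0], [4, 4, 6], [1, 1, 0], [0.0, 0.0, 0.0])
        assert cox_partial_loglik(rows, [0, 0]) == pytest.approx(-np.log(3) - np.log(2))

    def test_empty_risk_set_is_an_error(self):
        rows = toy_rows([6.0], [6.0], [1], [0.0])  # zero-length interval
        with pytest.raises(ValueError, match="risk set"):
            cox_partial_loglik(rows, [0, 0])


class TestTertiles:
    def test_symmetric_grid(self):
        scheme = tertile_cut(np.arange(1, 10))
        assert scheme.cut1 == pytest.approx(11 / 3)
        assert scheme.cut2 == pytest.approx(19 / 3)
        labels = scheme.assign(np.arange(1, 10))
        assert list(labels) == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            tertile_cut([5.0, 5.0, 5.0, 5.0])

    def test_balanced_group_counts(self):
        values = np.random.default_rng(0).gamma(3, 40, 999)
        labels = tertile_cut(values).assign(values)
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_invariant_under_monotone_transform(self):
        values = np.random.default_rng(1).gamma(3, 40, 500)
        l_raw = tertile_cut(values).assign(values)
        l_sqrt = tertile_cut(np.sqrt(values)).assign(np.sqrt(values))
        assert (l_raw == l_sqrt).all()


class TestCountingProcess:
    def test_single_visit_single_row(self):
        subject = make_subject(entry=50.0, exit_age=56.0, event=1)
        visits = make_visits(ages=(50.0,), nd=(100.0,), d=(25.0,))
        rows = expand_counting_process(subject, visits)
        assert len(rows) == 1
        assert rows.iloc[0]["age_start"] == 50.0
        assert rows.iloc[0]["age_stop"] == 56.0
        assert rows.iloc[0]["event_in_interval"] == 1

    def test_manual_three_visit_expansion(self):
        subject = make_subject(entry=50.0, exit_age=55.0, event=1)
        visits = make_visits(ages=(50.0, 52.0, 54.0), nd=(100, 110, 120), d=(25, 24, 23))
        rows = expand_counting_process(subject, visits)
        assert list(rows["age_start"]) == [50.0, 52.0, 54.0]
        assert list(rows["age_stop"]) == [52.0, 54.0, 55.0]
        assert list(rows["event_in_interval"]) == [0, 0, 1]
        assert np.allclose(rows["sqrt_nd"], np.sqrt([100, 110, 120]))
        # the intervals partition (entry, exit]
        assert (rows["age_stop"] - rows["age_start"]).sum() == pytest.approx(5.0)

    def test_visit_after_exit_is_an_error(self):
        subject = make_subject(entry=50.0, exit_age=53.0, event=0)
        visits = make_visits(ages=(50.0, 54.0), nd=(100, 100), d=(25, 25))
        with pytest.raises(ValueError, match="after exit"):
            expand_counting_process(subject, visits)


def _simple_ph_cohort(n=2000, beta=0.35, seed=0):
    """Exponential proportional-hazards data with a single baseline marker,
    wrapped in the cohort schema; the generating log-HR is the oracle."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    lam = 0.05 * np.exp(beta * x)
    t = rng.exponential(1 / lam)
    cens = 8.0
    event = (t < cens).astype(int)
    exit_age = 50.0 + np.minimum(t, cens)
    subjects = pd.DataFrame(
        dict(id=[f"S{i}" for i in range(n)], entry_age=50.0, exit_age=exit_age,
             event=event, bmi=25.0, hrt="never", fh="no", menopause="post", parity="2")
    )
    visits = pd.DataFrame(
        dict(id=subjects["id"], age=50.0, nd_area=(x + 12.0) ** 2,
             d_area=30.0 + rng.normal(0, 1, n) ** 2, bmi=np.nan)
    )
    return subjects, visits, beta


class TestFitCox:
    def test_recovers_generating_log_hazard_ratio(self):
        subjects, visits, beta = _simple_ph_cohort()
        fit = fit_cox(subjects, visits, "baseline_continuous")
        i = fit.param_names.index("sqrt_nd")
        est, se = fit.theta[i], fit.se("sqrt_nd")
        assert abs(est - beta) < 2 * se

    def test_null_covariate_gives_unit_hr(self):
        subjects, visits, _ = _simple_ph_cohort(n=1500, beta=0.0, seed=3)
        fit = fit_cox(subjects, visits, "baseline_continuous")
        row = next(r for r in fit.hr_rows if r["term"] == "sqrt_nd")
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_extended_equals_baseline_with_single_visits(self):
        subjects, visits, _ = _simple_ph_cohort(n=400, seed=4)
        f_base = fit_cox(subjects, visits, "baseline_continuous")
        f_ext = fit_cox(subjects, visits, "extended")
        for term in ("sqrt_nd", "sqrt_d"):
            assert f_ext.estimates[term] == pytest.approx(f_base.estimates[term], abs=1e-6)

    def test_lifelines_optimum_maximizes_reference_partial_loglik(self):
        """The lifelines coefficient vector sits at the maximum of the
        independently implemented Efron partial likelihood."""
        subjects, visits, _ = _simple_ph_cohort(n=300, seed=5)
        rows = pd.concat(
            [
                expand_counting_process(row, visits[visits["id"] == row["id"]])
                for _, row in subjects.iterrows()
            ],
            ignore_index=True,
        )
        fit = fit_cox(subjects, visits, "baseline_continuous")
        bhat = np.array([fit.estimates["sqrt_nd"], fit.estimates["sqrt_d"]])
        ll_hat = cox_partial_loglik(rows, bhat)
        for d in np.eye(2):
            for s in (+1e-3, -1e-3):
                assert cox_partial_loglik(rows, bhat + s * d) < ll_hat

    def test_tertile_mode_reports_joint_wald(self, small_cohort):
        _, subjects, visits, _ = small_cohort
        fit = fit_cox(subjects, visits, "baseline_tertile")
        res = fit.options["nda_tertile_wald"]
        assert res["df"] == 2 and res["chi2"] >= 0
        assert {"nd_T2", "nd_T3", "d_T2", "d_T3"} <= set(fit.param_names)


class TestReverseKM:
    def test_all_censored_at_ten_years(self):
        subjects = pd.DataFrame(
            dict(id=list("abcd"), entry_age=50.0, exit_age=60.0, event=0)
        )
        median, _ = reverse_km_median_followup(subjects)
        assert median == pytest.approx(10.0)

    def test_matches_hand_computed_table(self):
        # durations 2,3,4,5,6,7; censored flags 1,0,1,0,1,1 (reverse-KM events)
        subjects = pd.DataFrame(
            dict(id=list("abcdef"), entry_age=50.0,
                 exit_age=[52.0, 53.0, 54.0, 55.0, 56.0, 57.0],
                 event=[0, 1, 0, 1, 0, 0])
        )
        # survival of "still uncensored": S(2)=5/6, S(4)=5/8*... -> 5/6*3/4=0.625,
        # S(6)=0.625*1/2=0.3125 -> median 6
        median, _ = reverse_km_median_followup(subjects)
        assert median == pytest.approx(6.0)

    def test_events_do_not_add_reverse_drops(self):
        subjects = pd.DataFrame(
            dict(id=list("abcd"), entry_age=50.0, exit_age=[52.0, 54.0, 56.0, 58.0],
                 event=[0, 0, 0, 0])
        )
        m_all_cens, _ = reverse_km_median_followup(subjects)
        flipped = subjects.assign(event=[1, 0, 0, 0])
        m_flip, _ = reverse_km_median_followup(flipped)
        assert m_flip >= m_all_cens

    def test_requires_a_censored_subject(self):
        subjects = pd.DataFrame(dict(id=["a"], entry_age=50.0, exit_age=55.0, event=[1]))
        with pytest.raises(ValueError):
            reverse_km_median_followup(subjects)


class TestNestedCaseControl:
    def test_full_risk_set_approaches_cox(self):
        subjects, visits, _ = _simple_ph_cohort(n=600, seed=6)
        cox = fit_cox(subjects, visits, "baseline_continuous")
        matched = nested_case_control(
            subjects, visits, m_controls=np.inf, entry_age_band=None,
            rng=np.random.default_rng(0),
        )
        clogit = conditional_logistic_fit(matched)
        assert clogit.estimates["sqrt_nd"] == pytest.approx(
            cox.estimates["sqrt_nd"], abs=0.02
        )

    def test_single_pair_matches_grid_maximum(self):
        matched = pd.DataFrame(
            dict(set=[0, 0], case=[1, 0], sqrt_nd=[1.3, 0.9], sqrt_d=[0.0, 0.0])
        )
        fit = conditional_logistic_fit(matched, covariates=("sqrt_nd",))
        grid = np.linspace(-30, 30, 20001)
        d = 1.3 - 0.9
        ll = d * grid - np.log(1 + np.exp(d * grid))
        # a lone discordant pair has a monotone likelihood; statsmodels should
        # land where the gridded likelihood stops improving materially
        assert ll[np.argmin(np.abs(grid - fit.theta[0]))] >= ll.max() - 1e-3

    def test_permuted_exposure_within_sets_is_null(self):
        subjects, visits, _ = _simple_ph_cohort(n=800, seed=7)
        matched = nested_case_control(subjects, visits, m_controls=4,
                                      rng=np.random.default_rng(1))
        rng = np.random.default_rng(2)
        permuted = matched.copy()
        permuted["sqrt_nd"] = (
            permuted.groupby("set")["sqrt_nd"].transform(
                lambda s: s.to_numpy()[rng.permutation(len(s))]
            )
        )
        fit = conditional_logistic_fit(permuted, covariates=("sqrt_nd",))
        assert abs(fit.theta[0]) < 2.5 * np.sqrt(fit.vcov[0, 0])

    def test_small_risk_sets_kept_with_fewer_controls(self):
        subjects, visits, _ = _simple_ph_cohort(n=30, seed=8)
        matched = nested_case_control(subjects, visits, m_controls=50,
                                      rng=np.random.default_rng(0))
        sizes = matched.groupby("set").size()
        assert (sizes >= 1).all() and sizes.max() <= 30
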