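"""Classic survival comparison analyses.

These are the standard designs the joint model is compared against:

* model 1 — Cox proportional hazards on the age scale with delayed entry,
  baseline (first-mammogram) sqrt-area values entered linearly;
* model 2 — the same with dense/nondense areas categorized into tertiles
  computed over the entire analysis sample;
* model 3 — extended Cox with time-updated covariates in the counting-process
  formulation (values carried forward between visits);
* reverse Kaplan-Meier follow-up summaries; and a nested case-control design
  with incidence-density sampling and conditional logistic regression.

Model fitting is delegated to lifelines (Cox) and statsmodels (conditional
logistic); the partial likelihood itself is implemented here independently so
small instances can be checked against explicit risk-set enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .jointmodel import FitResult, joint_wald_test, wald_inference
from .splines import covariate_matrix

__all__ = [
    "TertileScheme",
    "tertile_cut",
    "expand_counting_process",
    "cox_partial_loglik",
    "fit_cox",
    "reverse_km_median_followup",
    "nested_case_control",
    "conditional_logistic_fit",
]


# --------------------------------------------------------------------------
# tertiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TertileScheme:
    """Tertile cut points on the raw cm^2 scale, with their provenance."""

    cut1: float
    cut2: float
    provenance: str = "entire sample"

    def assign(self, values) -> np.ndarray:
        """Left-closed assignment: T1 = [min, cut1), T2 = [cut1, cut2), T3 = rest."""
        values = np.asarray(values, dtype=float)
        return np.where(values < self.cut1, "T1", np.where(values < self.cut2, "T2", "T3"))


def tertile_cut(values, provenance: str = "entire sample") -> TertileScheme:
    """Cut points at the 1/3 and 2/3 sample quantiles (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 3:
        raise ValueError("need at least 3 distinct values to form tertiles")
    c1, c2 = np.quantile(values, [1 / 3, 2 / 3])
    return TertileScheme(float(c1), float(c2), provenance)


# --------------------------------------------------------------------------
# counting-process expansion
# --------------------------------------------------------------------------


def expand_counting_process(subject, visits: pd.DataFrame) -> pd.DataFrame:
    """(start, stop] rows for one subject with last-value-carried-forward
    covariates; the final row ends at exit_age and carries the event flag."""
    v = visits.sort_values("age").reset_index(drop=True)
    entry, exit_age = float(subject["entry_age"]), float(subject["exit_age"])
    event = int(subject["event"])
    ages = v["age"].to_numpy(dtype=float)
    if len(ages) == 0:
        raise ValueError(f"subject {subject['id']!r} has no visits")
    if np.any(ages > exit_age + 1e-9):
        raise ValueError(f"subject {subject['id']!r} has a visit after exit_age")
    starts = np.maximum(ages, entry)
    stops = np.concatenate([starts[1:], [exit_age]])
    keep = stops > starts
    rows = pd.DataFrame(
        {
            "id": subject["id"],
            "age_start": starts[keep],
            "age_stop": stops[keep],
            "event_in_interval": 0,
            "sqrt_nd": np.sqrt(v["nd_area"].to_numpy(dtype=float))[keep],
            "sqrt_d": np.sqrt(v["d_area"].to_numpy(dtype=float))[keep],
        }
    )
    if len(rows) == 0:
        # degenerate follow-up (exit == entry): keep a zero-length-protected row
        rows = pd.DataFrame(
            {
                "id": [subject["id"]],
                "age_start": [entry],
                "age_stop": [entry + 1e-8],
                "event_in_interval": [0],
                "sqrt_nd": [np.sqrt(float(v["nd_area"].iloc[0]))],
                "sqrt_d": [np.sqrt(float(v["d_area"].iloc[0]))],
            }
        )
    rows.iloc[-1, rows.columns.get_loc("event_in_interval")] = event
    return rows


# --------------------------------------------------------------------------
# Efron partial likelihood (independent reference implementation)
# --------------------------------------------------------------------------


def cox_partial_loglik(rows: pd.DataFrame, beta, covariates=("sqrt_nd", "sqrt_d")) -> float:
    """Efron-tie Cox partial log-likelihood on counting-process rows.

    Rows are (age_start, age_stop] intervals; a subject is at risk at an event
    age t when age_start < t <= age_stop, which encodes delayed entry.
    Baseline-only models are the special case of one interval per subject.
    """
    beta = np.asarray(beta, dtype=float)
    X = rows[list(covariates)].to_numpy(dtype=float)
    eta = X @ beta
    start = rows["age_start"].to_numpy(dtype=float)
    stop = rows["age_stop"].to_numpy(dtype=float)
    event = rows["event_in_interval"].to_numpy(dtype=int)
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        tied = (event == 1) & (stop == t)
        at_risk = (start < t) & (t <= stop)
        if not at_risk.any():
            raise ValueError(f"empty risk set at event age {t}")
        d = int(tied.sum())
        e_risk = np.exp(eta[at_risk]).sum()
        e_tied = np.exp(eta[tied]).sum()
        ll += eta[tied].sum()
        for ell in range(d):
            ll -= np.log(e_risk - (ell / d) * e_tied)
    return float(ll)


# --------------------------------------------------------------------------
# model fitting (lifelines behind the shared FitResult surface)
# --------------------------------------------------------------------------


def _baseline_table(subjects: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    first = visits.sort_values("age").groupby("id", as_index=False).first()
    out = subjects.merge(
        first[["id", "nd_area", "d_area"]], on="id", validate="1:1"
    )
    out["sqrt_nd"] = np.sqrt(out["nd_area"])
    out["sqrt_d"] = np.sqrt(out["d_area"])
    return out


_ADJUSTERS = ("bmi_baseline", "hrt", "fh")


def _drop_constant_columns(df: pd.DataFrame, keep=()) -> tuple[pd.DataFrame, list]:
    """Zero-variance covariates (e.g. an unused dummy level) make the partial
    likelihood unidentifiable; drop them and report which were dropped."""
    dropped = [
        c for c in df.columns
        if c not in keep and df[c].dtype.kind in "fiu" and df[c].nunique() <= 1
    ]
    return df.drop(columns=dropped), dropped


def _adjuster_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    W, names = covariate_matrix(subjects, _ADJUSTERS)
    return pd.DataFrame(W, columns=names, index=subjects.index)


def fit_cox(
    subjects: pd.DataFrame,
    visits: pd.DataFrame,
    mode: str = "baseline_continuous",
    tertiles: dict | None = None,
) -> FitResult:
    """Cox models 1-3 on the age scale with delayed entry.

    mode="baseline_continuous" : first-visit sqrt areas, linear (model 1)
    mode="baseline_tertile"    : first-visit raw-area tertiles (model 2);
                                 full-sample cut points may be passed in
                                 `tertiles` (e.g. when fitting a subgroup)
    mode="extended"            : counting-process time-updated sqrt areas
                                 (model 3)
    """
    if mode in ("baseline_continuous", "baseline_tertile"):
        base = _baseline_table(subjects, visits).reset_index(drop=True)
        df = pd.concat(
            [
                base[["entry_age", "exit_age", "event"]],
                _adjuster_frame(base),
            ],
            axis=1,
        )
        if mode == "baseline_continuous":
            df["sqrt_nd"] = base["sqrt_nd"]
            df["sqrt_d"] = base["sqrt_d"]
            exposure_terms = ["sqrt_nd", "sqrt_d"]
        else:
            if tertiles is None:
                tertiles = {
                    "nd": tertile_cut(base["nd_area"]),
                    "d": tertile_cut(base["d_area"]),
                }
            for mk in ("nd", "d"):
                lab = tertiles[mk].assign(base[f"{mk}_area"])
                for t in ("T2", "T3"):
                    df[f"{mk}_{t}"] = (lab == t).astype(float)
            exposure_terms = ["nd_T2", "nd_T3", "d_T2", "d_T3"]
        df, dropped = _drop_constant_columns(df, keep=("entry_age", "exit_age", "event"))
        fitter = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(
                df, duration_col="exit_age", event_col="event", entry_col="entry_age"
            )
        names = list(fitter.params_.index)
        theta = fitter.params_.to_numpy()
        vcov = fitter.variance_matrix_.to_numpy()
        loglik = float(fitter.log_likelihood_)
    elif mode == "extended":
        pieces = [
            expand_counting_process(row, visits[visits["id"] == row["id"]])
            for _, row in subjects.iterrows()
        ]
        cp = pd.concat(pieces, ignore_index=True)
        adj = _adjuster_frame(subjects.reset_index(drop=True))
        adj["id"] = subjects["id"].to_numpy()
        cp = cp.merge(adj, on="id", validate="m:1")
        cp, dropped = _drop_constant_columns(
            cp, keep=("id", "age_start", "age_stop", "event_in_interval")
        )
        fitter = CoxTimeVaryingFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(
                cp,
                id_col="id",
                event_col="event_in_interval",
                start_col="age_start",
                stop_col="age_stop",
            )
        names = list(fitter.params_.index)
        theta = fitter.params_.to_numpy()
        vcov = fitter.variance_matrix_.to_numpy()
        loglik = float(fitter.log_likelihood_)
        exposure_terms = ["sqrt_nd", "sqrt_d"]
    else:
        raise ValueError(f"unknown Cox mode {mode!r}")

    convergence_issue = any("onvergence" in str(w.message) for w in caught)
    exposure_terms = [t for t in exposure_terms if t not in dropped]
    fit = FitResult(
        model={"baseline_continuous": "m1", "baseline_tertile": "m2", "extended": "m3"}[mode],
        param_names=names,
        theta=theta,
        free=np.ones(len(names), dtype=bool),
        loglik=loglik,
        converged=not convergence_issue,
        n_iter=0,
        grad_inf=np.nan,
        vcov=vcov,
        options=dict(mode=mode, ties="efron", exposure_terms=exposure_terms),
    )
    wald_inference(fit, terms=names)
    if mode == "baseline_tertile":
        fit.options["nda_tertile_wald"] = joint_wald_test(fit, ["nd_T2", "nd_T3"])
    return fit


# --------------------------------------------------------------------------
# follow-up summary
# --------------------------------------------------------------------------


def reverse_km_median_followup(subjects: pd.DataFrame):
    """Median follow-up (years) by the reverse Kaplan-Meier method.

    Censoring is treated as the event and events are censored, on the
    follow-up-duration scale; returns (median, (ci_low, ci_high)), with NaN
    for a median that is never reached.
    """
    duration = (subjects["exit_age"] - subjects["entry_age"]).to_numpy(dtype=float)
    censored = 1 - subjects["event"].to_numpy(dtype=int)
    if censored.sum() == 0:
        raise ValueError("reverse Kaplan-Meier needs at least one censored subject")
    kmf = KaplanMeierFitter()
    kmf.fit(duration, event_observed=censored)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return median, (lo, hi)


# --------------------------------------------------------------------------
# nested case-control
# --------------------------------------------------------------------------


def nested_case_control(
    subjects: pd.DataFrame,
    visits: pd.DataFrame,
    m_controls: int = 2,
    entry_age_band: float | None = 2.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Incidence-density sampling of controls for each case.

    For every case, controls are drawn without replacement from subjects at
    risk at the case's event age (entry < t <= exit, excluding the case),
    optionally matched on entry age within +/- `entry_age_band` years.  Risk
    sets smaller than `m_controls` are kept with fewer controls.  Covariates
    are the baseline sqrt areas plus the usual adjusters.
    """
    rng = rng or np.random.default_rng(0)
    base = _baseline_table(subjects, visits).reset_index(drop=True)
    adj = _adjuster_frame(base)
    entry = base["entry_age"].to_numpy(dtype=float)
    exit_age = base["exit_age"].to_numpy(dtype=float)
    event = base["event"].to_numpy(dtype=int)
    sets = []
    case_rows = np.flatnonzero(event == 1)
    for set_id, ci in enumerate(case_rows):
        t = exit_age[ci]
        at_risk = (entry < t) & (t <= exit_age)
        at_risk[ci] = False
        if entry_age_band is not None:
            at_risk &= np.abs(entry - entry[ci]) <= entry_age_band
        pool = np.flatnonzero(at_risk)
        m = min(m_controls, pool.size) if np.isfinite(m_controls) else pool.size
        chosen = (
            pool if m == pool.size else rng.choice(pool, size=int(m), replace=False)
        )
        members = np.concatenate([[ci], chosen])
        block = pd.concat([base.loc[members, ["id", "sqrt_nd", "sqrt_d"]],
                           adj.loc[members]], axis=1)
        block.insert(0, "set", set_id)
        block.insert(1, "case", [1] + [0] * len(chosen))
        sets.append(block)
    if not sets:
        raise ValueError("no cases in the data; cannot build a nested case-control set")
    return pd.concat(sets, ignore_index=True)


def conditional_logistic_fit(
    matched: pd.DataFrame, covariates=("sqrt_nd", "sqrt_d")
) -> FitResult:
    """Exact set-conditional logistic regression on matched sets."""
    from statsmodels.discrete.conditional_models import ConditionalLogit

    usable = matched.groupby("set")["case"].transform(lambda s: 0 < s.sum() < len(s))
    df = matched[usable]
    model = ConditionalLogit(
        df["case"].to_numpy(), df[list(covariates)].to_numpy(), groups=df["set"].to_numpy()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    fit = FitResult(
        model="ncc",
        param_names=list(covariates),
        theta=np.asarray(res.params, dtype=float),
        free=np.ones(len(covariates), dtype=bool),
        loglik=float(res.llf),
        converged=bool(getattr(res, "converged", True)),
        n_iter=0,
        grad_inf=np.nan,
        vcov=np.asarray(res.cov_params(), dtype=float),
        options=dict(n_sets=int(matched["set"].nunique())),
    )
    wald_inference(fit, terms=list(covariates))
    return fit
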