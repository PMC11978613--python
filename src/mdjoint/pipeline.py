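"""Cohort I/O, subgroup construction, the five-model analysis run, and the
parameter-recovery experiment harness.

The five comparison models:

  m1  baseline Cox, continuous sqrt areas        (first mammogram only)
  m2  baseline Cox, full-sample tertiles         (first mammogram only)
  m3  extended Cox, counting-process updates
  m4  bivariate joint model (nondense + dense)
  m5  trivariate joint model (+ BMI trajectory)

Subgroups follow the menopausal-status definitions evaluated at baseline:
postmenopausal women, and premenopausal women under age 50 at entry.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coxmodels
from .datagen import SyntheticConfig, generate_dataset
from .jointmodel import FitResult, fit_joint_model
from .splines import CATEGORICAL_LEVELS, MarkerSpec

__all__ = [
    "read_cohort",
    "write_cohort",
    "make_subgroups",
    "AnalysisConfig",
    "run_analysis",
    "recovery_experiment",
    "derived_se",
]

SUBJECT_COLUMNS = [
    "id", "entry_age", "exit_age", "event", "bmi", "hrt", "fh", "menopause", "parity",
]
VISIT_COLUMNS = ["id", "age", "nd_area", "d_area", "bmi"]

MODELS = ("m1", "m2", "m3", "m4", "m5")
SUBGROUPS = ("full", "postmenopausal", "premenopausal_under50")


# --------------------------------------------------------------------------
# I/O and validation
# --------------------------------------------------------------------------


def _fail_rows(mask, frame, message):
    if mask.any():
        rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:5]]
        raise ValueError(f"{message} (rows {rows}{'...' if mask.sum() > 5 else ''})")


def read_cohort(subjects_path, visits_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the two flat tables; joins on `id`.

    Raises a data error naming the offending rows for orphan visits,
    non-monotone or out-of-range visit ages, and negative areas.
    """
    subjects = pd.read_csv(subjects_path, dtype={"id": str})
    visits = pd.read_csv(visits_path, dtype={"id": str})
    missing = set(SUBJECT_COLUMNS) - set(subjects.columns)
    if missing:
        raise ValueError(f"{subjects_path}: missing subject columns {sorted(missing)}")
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValueError(f"{visits_path}: missing visit columns {sorted(missing)}")

    if subjects["id"].duplicated().any():
        raise ValueError(f"{subjects_path}: duplicated subject ids")
    _fail_rows(~subjects["entry_age"].between(40, 74), subjects,
               "entry_age outside the 40-74 screening window")
    _fail_rows(subjects["exit_age"] < subjects["entry_age"], subjects,
               "exit_age before entry_age")
    _fail_rows(~subjects["event"].isin([0, 1]), subjects, "event flag not 0/1")
    for cov in ("hrt", "fh", "menopause", "parity"):
        _fail_rows(~subjects[cov].astype(str).isin(CATEGORICAL_LEVELS[cov]), subjects,
                   f"unknown {cov} level")

    _fail_rows(~visits["id"].isin(set(subjects["id"])), visits, "orphan visit ids")
    _fail_rows(visits["nd_area"] < 0, visits, "negative nondense area")
    _fail_rows(visits["d_area"] < 0, visits, "negative dense area")
    merged = visits.merge(subjects[["id", "entry_age", "exit_age"]], on="id")
    _fail_rows(merged["age"] > merged["exit_age"] + 1e-9, visits, "visit age after exit_age")
    _fail_rows(merged["age"] < merged["entry_age"] - 1e-9, visits, "visit age before entry_age")
    bad_order = visits.groupby("id")["age"].apply(
        lambda a: bool((np.diff(a.to_numpy()) <= 0).any())
    )
    if bad_order.any():
        raise ValueError(
            f"non-increasing visit ages for subjects {list(bad_order[bad_order].index[:5])}"
        )
    no_visits = set(subjects["id"]) - set(visits["id"])
    if no_visits:
        raise ValueError(f"subjects without any visit: {sorted(no_visits)[:5]}")
    return subjects, visits


def write_cohort(subjects, visits, outdir, truth=None) -> dict:
    """Write subjects.csv / visits.csv (and truth.json for synthetic data)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "visits": outdir / "visits.csv",
    }
    subjects.to_csv(paths["subjects"], index=False, float_format="%.10g")
    visits.to_csv(paths["visits"], index=False, float_format="%.10g")
    if truth is not None:
        p = truth["params"]
        record = {
            "markers": list(p.markers),
            "alpha": {k: float(v) for k, v in p.alpha.items()},
            "gamma": {k: float(v) for k, v in p.gamma.items()},
            "beta": {k: list(map(float, v)) for k, v in p.beta.items()},
            "omega": list(map(float, p.omega)),
            "Sigma_b": p.Sigma_b.tolist(),
            "Sigma_eps": p.Sigma_eps.tolist(),
            "b": truth["b"],
        }
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(record, fh)
    return paths


# --------------------------------------------------------------------------
# subgroups
# --------------------------------------------------------------------------


def make_subgroups(subjects: pd.DataFrame, which=SUBGROUPS) -> dict[str, pd.DataFrame]:
    """Named baseline subgroups.

    postmenopausal: menopause == "post" at entry; premenopausal_under50:
    menopause == "pre" and entry_age strictly < 50.  Perimenopausal women
    appear in the full cohort only.
    """
    groups = {}
    for name in which:
        if name == "full":
            groups[name] = subjects
        elif name == "postmenopausal":
            groups[name] = subjects[subjects["menopause"] == "post"]
        elif name == "premenopausal_under50":
            groups[name] = subjects[
                (subjects["menopause"] == "pre") & (subjects["entry_age"] < 50)
            ]
        else:
            raise ValueError(f"unknown subgroup {name!r}")
    return groups


# --------------------------------------------------------------------------
# the five-model analysis
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """What to run: input data (paths or a synthetic config), models,
    subgroups, numerical options, output directory."""

    subjects_path: str | None = None
    visits_path: str | None = None
    synthetic: SyntheticConfig | None = None
    models: tuple = MODELS
    subgroups: tuple = ("full",)
    n_ghq: int = 7
    n_gl: int = 15
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        unknown = set(self.subgroups) - set(SUBGROUPS)
        if unknown:
            raise ValueError(f"unknown subgroups {sorted(unknown)}")
        if self.synthetic is None and (self.subjects_path is None or self.visits_path is None):
            raise ValueError("provide either data paths or a synthetic config")


def _load(config: AnalysisConfig):
    if config.synthetic is not None:
        subjects, visits, _ = generate_dataset(config.synthetic)
        return subjects, visits
    return read_cohort(config.subjects_path, config.visits_path)


def _joint_specs(trivariate: bool):
    specs = [
        MarkerSpec("nd", "sqrt", 5, ("bmi_baseline", "hrt", "fh")),
        MarkerSpec("d", "sqrt", 5, ("bmi_baseline", "hrt", "fh")),
    ]
    if trivariate:
        specs.append(MarkerSpec("bmi", "identity", 5, ("bmi_baseline",)))
    return specs


def _fit_one(model, subjects, visits, config, tertiles):
    if model == "m1":
        return coxmodels.fit_cox(subjects, visits, "baseline_continuous")
    if model == "m2":
        return coxmodels.fit_cox(subjects, visits, "baseline_tertile", tertiles=tertiles)
    if model == "m3":
        return coxmodels.fit_cox(subjects, visits, "extended")
    if model in ("m4", "m5"):
        trivariate = model == "m5"
        if trivariate and not np.isfinite(visits["bmi"]).any():
            raise ValueError("model m5 needs visit-level BMI measurements")
        return fit_joint_model(
            subjects,
            visits,
            _joint_specs(trivariate),
            n_ghq=config.n_ghq,
            n_gl=config.n_gl,
            model_label=model,
        )
    raise ValueError(f"unknown model {model!r}")


_EXPOSURE_TERMS = {
    "m1": {"sqrt_nd": "NDA", "sqrt_d": "DA"},
    "m2": {"nd_T2": "NDA T2", "nd_T3": "NDA T3", "d_T2": "DA T2", "d_T3": "DA T3"},
    "m3": {"sqrt_nd": "NDA", "sqrt_d": "DA"},
    "m4": {"alpha:nd": "NDA", "alpha:d": "DA"},
    "m5": {"alpha:nd": "NDA", "alpha:d": "DA", "alpha:bmi": "BMI"},
}


def run_analysis(config: AnalysisConfig):
    """Run the requested models on the requested subgroups.

    Returns (results_table, fits, metadata).  Failures are recorded per
    (model, subgroup) cell and the run continues.
    """
    subjects, visits = _load(config)
    groups = make_subgroups(subjects, config.subgroups)
    # model-2 tertiles always come from the entire analysis sample
    base = visits.sort_values("age").groupby("id", as_index=False).first()
    tertiles = {
        "nd": coxmodels.tertile_cut(base["nd_area"]),
        "d": coxmodels.tertile_cut(base["d_area"]),
    }
    rows, fits, meta = [], {}, {}
    for gname, gsub in groups.items():
        gvis = visits[visits["id"].isin(set(gsub["id"]))]
        fu_median, fu_ci = (np.nan, (np.nan, np.nan))
        if (gsub["event"] == 0).any():
            fu_median, fu_ci = coxmodels.reverse_km_median_followup(gsub)
        meta[gname] = dict(
            n_subjects=int(len(gsub)),
            n_events=int(gsub["event"].sum()),
            n_mammograms=int(len(gvis)),
            median_followup=float(fu_median),
            median_followup_ci=[float(fu_ci[0]), float(fu_ci[1])],
        )
        print(
            f"[mdjoint] subgroup {gname}: n={len(gsub)} events={gsub['event'].sum()} "
            f"mammograms={len(gvis)} median follow-up={fu_median:.2f} y",
            file=sys.stderr,
        )
        for model in config.models:
            try:
                fit = _fit_one(model, gsub, gvis, config, tertiles)
                fits[(model, gname)] = fit
                wanted = _EXPOSURE_TERMS[model]
                for r in fit.hr_rows:
                    if r["term"] in wanted:
                        rows.append(
                            dict(
                                model=model, subgroup=gname, term=wanted[r["term"]],
                                HR=r["HR"], ci_low=r["ci_low"], ci_high=r["ci_high"],
                                p=r["p"], converged=fit.converged,
                            )
                        )
            except Exception as exc:  # failure is a result, not a crash
                rows.append(
                    dict(model=model, subgroup=gname, term="ERROR", HR=np.nan,
                         ci_low=np.nan, ci_high=np.nan, p=np.nan, converged=False,
                         error=str(exc))
                )
    table = pd.DataFrame(rows)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        manifest = dict(
            seed=config.seed,
            models=list(config.models),
            subgroups=list(config.subgroups),
            metadata=meta,
            config_hash=hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        for (model, gname), fit in fits.items():
            fit.to_json(out / f"fit_{model}_{gname}.json")
    return table, fits, meta


# --------------------------------------------------------------------------
# parameter-recovery harness
# --------------------------------------------------------------------------


def derived_se(fit: FitResult, func) -> float:
    """Delta-method SE of a scalar function of the packed parameters."""
    if fit.vcov is None:
        return np.nan
    theta = fit.theta
    g = np.zeros(len(theta))
    idx = np.flatnonzero(fit.free)
    for i in idx:
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (func(fit.transform.unpack(tp)) - func(fit.transform.unpack(tm))) / (2 * h)
    V = fit.vcov[np.ix_(idx, idx)]
    return float(np.sqrt(g[idx] @ V @ g[idx]))


def recovery_experiment(
    base_config: SyntheticConfig,
    n_replicates: int = 10,
    markers=("nd", "d"),
    seed: int = 1,
    n_ghq: int = 7,
    n_gl: int = 15,
    compute_vcov: bool = True,
    use_true_knots: bool = True,
) -> pd.DataFrame:
    """Simulate-and-refit: per-parameter mean estimate, bias, empirical SE,
    mean model SE, and 95% CI coverage over replicate cohorts.

    Tracked parameters: the association coefficients and the random-intercept
    and measurement-error correlations of the nondense/dense pair.
    """
    import dataclasses

    truth_params = base_config.true_params()
    targets = {f"alpha:{k}": truth_params.alpha[k] for k in markers}
    targets["corr_b"] = truth_params.corr_b()
    targets["corr_eps"] = truth_params.corr_eps()
    records = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(base_config, seed=int(seed + r) % (2**31))
        subjects, visits, truth = generate_dataset(cfg)
        design = cfg.design(markers) if use_true_knots else None
        specs = [cfg.specs()[k] for k in markers]
        try:
            fit = fit_joint_model(
                subjects, visits, specs, design=design,
                n_ghq=n_ghq, n_gl=n_gl, compute_vcov=compute_vcov,
            )
        except Exception as exc:
            records.append(dict(replicate=r, failed=True, error=str(exc)))
            continue
        p = fit.params()
        rec = dict(replicate=r, failed=False, converged=fit.converged,
                   loglik=fit.loglik, n_events=int(subjects["event"].sum()))
        for k in markers:
            rec[f"alpha:{k}"] = float(p.alpha[k])
            rec[f"se_alpha:{k}"] = fit.se(f"alpha:{k}")
        rec["corr_b"] = float(p.corr_b())
        rec["corr_eps"] = float(p.corr_eps())
        if compute_vcov:
            rec["se_corr_b"] = derived_se(fit, lambda q: q.corr_b())
            rec["se_corr_eps"] = derived_se(fit, lambda q: q.corr_eps())
        records.append(rec)
    reps = pd.DataFrame.from_records(records)
    ok = reps[~reps["failed"]] if "failed" in reps else reps
    rows = []
    for name, truth_val in targets.items():
        est = ok[name].to_numpy(dtype=float)
        se_col = f"se_{name}" if f"se_{name}" in ok else None
        ses = ok[se_col].to_numpy(dtype=float) if se_col else np.full(len(est), np.nan)
        cover = np.nan
        if np.isfinite(ses).all() and len(est):
            cover = float(
                np.mean((est - 1.96 * ses <= truth_val) & (truth_val <= est + 1.96 * ses))
            )
        rows.append(
            dict(
                parameter=name,
                truth=truth_val,
                mean_estimate=float(est.mean()) if len(est) else np.nan,
                bias=float(est.mean() - truth_val) if len(est) else np.nan,
                empirical_se=float(est.std(ddof=1)) if len(est) > 1 else np.nan,
                mean_model_se=(
                    float(np.nanmean(ses)) if np.isfinite(ses).any() else np.nan
                ),
                coverage_95=cover,
                n_replicates=int(len(est)),
            )
        )
    report = pd.DataFrame(rows)
    report.attrs["replicates"] = reps
    return report
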