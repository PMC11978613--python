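"""Shared-random-effects joint models for longitudinal markers and survival.

The model: for subject i and marker k (K = 2 or 3 markers), observations on
the transformed scale at visit ages t_ij are

    y_ikj = x_ik(t_ij)' beta_k + b_ik + eps_ikj,

with (b_i1..b_iK) ~ N(0, Sigma_b) shared random intercepts and within-visit
residual vectors eps ~ N(0, Sigma_eps), independent across visits.  The
hazard of breast cancer on the age scale is

    lambda_i(t) = exp( s0(t)' omega + w_i' gamma + sum_k alpha_k mu_ik(t) ),

where s0 is a natural cubic spline (explicit intercept + df basis columns),
w_i are baseline survival covariates, and mu_ik(t) = x_ik(t)'beta_k + b_ik
is the model-implied current marker mean ("expected value" association).
Left truncation at study entry is handled conditionally on b: the survival
factor integrates the hazard from entry age to exit age only.

Estimation maximizes the marginal likelihood, integrating b out per subject.
Because the hazard depends on b only through the scalar u = alpha' b, the
K-dimensional integral collapses exactly to a one-dimensional integral that
is evaluated with adaptive Gauss-Hermite quadrature; a direct K-dimensional
adaptive Gauss-Hermite implementation (`subject_loglik`) serves as the
readable per-subject reference path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import roots_hermite

from .splines import (
    MarkerSpec,
    NaturalSplineBasis,
    covariate_matrix,
    covariate_row,
    fixed_effects_matrix,
)

__all__ = [
    "JointParams",
    "ModelDesign",
    "FitResult",
    "hazard",
    "cumulative_hazard",
    "subject_loglik",
    "CohortLikelihood",
    "fit_joint_model",
    "wald_inference",
    "joint_wald_test",
]

LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# parameters and design
# --------------------------------------------------------------------------


@dataclass
class JointParams:
    """Complete parameter set of the K-marker joint model.

    beta     : marker name -> fixed-effect vector (intercept, spline, covariates)
    Sigma_b  : K x K random-intercept covariance
    Sigma_eps: K x K within-visit residual covariance
    omega    : log baseline-hazard spline coefficients (intercept + df columns)
    gamma    : survival covariate name -> coefficient
    alpha    : marker name -> association coefficient (per unit of the
               transformed marker scale)
    """

    markers: tuple[str, ...]
    beta: dict[str, np.ndarray]
    Sigma_b: np.ndarray
    Sigma_eps: np.ndarray
    omega: np.ndarray
    gamma: dict[str, float]
    alpha: dict[str, float]

    def __post_init__(self):
        K = len(self.markers)
        if K not in (2, 3):
            raise ValueError(f"joint model supports 2 or 3 markers, got {K}")
        self.Sigma_b = np.asarray(self.Sigma_b, dtype=float)
        self.Sigma_eps = np.asarray(self.Sigma_eps, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.beta = {k: np.asarray(v, dtype=float) for k, v in self.beta.items()}
        for name, S in (("Sigma_b", self.Sigma_b), ("Sigma_eps", self.Sigma_eps)):
            if S.shape != (K, K) or not np.allclose(S, S.T):
                raise ValueError(f"{name} must be a symmetric {K}x{K} matrix")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"{name} is not positive definite")
        if set(self.beta) != set(self.markers):
            raise ValueError("beta must have one vector per marker")
        if set(self.alpha) != set(self.markers):
            raise ValueError("alpha must have one coefficient per marker")
        if "bmi" in self.markers and "bmi_baseline" in self.gamma:
            raise ValueError(
                "the trivariate model replaces baseline BMI in the survival "
                "submodel by the BMI trajectory; remove gamma['bmi_baseline']"
            )

    @property
    def alpha_vec(self) -> np.ndarray:
        return np.array([self.alpha[k] for k in self.markers])

    def corr_b(self, k1: str = "nd", k2: str = "d") -> float:
        i, j = self.markers.index(k1), self.markers.index(k2)
        S = self.Sigma_b
        return S[i, j] / np.sqrt(S[i, i] * S[j, j])

    def corr_eps(self, k1: str = "nd", k2: str = "d") -> float:
        i, j = self.markers.index(k1), self.markers.index(k2)
        S = self.Sigma_eps
        return S[i, j] / np.sqrt(S[i, i] * S[j, j])


@dataclass
class ModelDesign:
    """Marker specifications plus the spline bases and survival covariates."""

    specs: dict[str, MarkerSpec]
    marker_basis: NaturalSplineBasis
    hazard_basis: NaturalSplineBasis
    survival_covariates: tuple[str, ...] = ("bmi_baseline", "hrt", "fh")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.specs)

    @classmethod
    def from_data(cls, subjects, visits, specs, survival_covariates=None, df=5):
        """Quantile-based knots: visit ages for the markers, event ages for
        the baseline hazard."""
        specs = {s.name: s for s in specs}
        if survival_covariates is None:
            survival_covariates = (
                ("hrt", "fh") if "bmi" in specs else ("bmi_baseline", "hrt", "fh")
            )
        marker_basis = NaturalSplineBasis.from_quantiles(visits["age"], df=df)
        event_ages = subjects.loc[subjects["event"] == 1, "exit_age"]
        if len(event_ages) < df + 1:
            event_ages = subjects["exit_age"]
        hazard_basis = NaturalSplineBasis.from_quantiles(event_ages, df=df, clip=None)
        return cls(specs, marker_basis, hazard_basis, tuple(survival_covariates))

    def hazard_design(self, ages) -> np.ndarray:
        """[1 | ns(age)] rows for the log baseline hazard."""
        ages = np.asarray(ages, dtype=float)
        B = self.hazard_basis.evaluate(ages.ravel())
        out = np.concatenate([np.ones((B.shape[0], 1)), B], axis=1)
        return out.reshape(ages.shape + (-1,))

    def marker_spline(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        B = self.marker_basis.evaluate(ages.ravel())
        return B.reshape(ages.shape + (-1,))


# --------------------------------------------------------------------------
# hazard and cumulative hazard (per-subject reference operations)
# --------------------------------------------------------------------------


def _subject_mu(ages, subject, design: ModelDesign, params: JointParams, b_i):
    """Marker means mu_ik(age) for one subject, shape (K, len(ages))."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    mus = []
    for j, k in enumerate(params.markers):
        X = fixed_effects_matrix(ages, subject, design.specs[k], design.marker_basis)
        mus.append(X @ params.beta[k] + b_i[j])
    return np.array(mus)


def hazard(age, subject, design: ModelDesign, params: JointParams, b_i) -> np.ndarray:
    """lambda_i(age) = exp(s0(age)'omega + w_i'gamma + sum_k alpha_k mu_ik(age))."""
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    b_i = np.asarray(b_i, dtype=float)
    eta = design.hazard_design(ages) @ params.omega
    w = covariate_row(subject, [c for c in design.survival_covariates])
    gamma_vec = _gamma_vector(design, params)
    eta = eta + w @ gamma_vec
    eta = eta + params.alpha_vec @ _subject_mu(ages, subject, design, params, b_i)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite hazard linear predictor")
    lam = np.exp(eta)
    return lam if np.ndim(age) else float(lam[0])


def _gamma_vector(design: ModelDesign, params: JointParams) -> np.ndarray:
    _, names = covariate_matrix_names(design)
    return np.array([params.gamma.get(nm, 0.0) for nm in names])


def covariate_matrix_names(design: ModelDesign):
    from .splines import CATEGORICAL_LEVELS

    names = []
    for cov in design.survival_covariates:
        if cov == "bmi_baseline":
            names.append("bmi_baseline")
        else:
            names += [f"{cov}_{lv}" for lv in CATEGORICAL_LEVELS[cov][1:]]
    return design.survival_covariates, names


def cumulative_hazard(
    a0: float,
    a1: float,
    subject,
    design: ModelDesign,
    params: JointParams,
    b_i,
    n_nodes: int = 30,
) -> float:
    """Gauss-Legendre integral of the hazard over [a0, a1]."""
    if a1 < a0:
        raise ValueError(f"a1 < a0 in cumulative_hazard ({a0}, {a1})")
    if a1 == a0:
        return 0.0
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    mid, half = 0.5 * (a0 + a1), 0.5 * (a1 - a0)
    return float(half * w @ hazard(mid + half * x, subject, design, params, b_i))


# --------------------------------------------------------------------------
# per-subject marginal log-likelihood (K-dimensional adaptive Gauss-Hermite)
# --------------------------------------------------------------------------


def _subject_arrays(subject, visits, design: ModelDesign, params: JointParams):
    """Residual-free design pieces for one subject: per-visit y, X beta means,
    observation masks, survival designs."""
    K = len(params.markers)
    ys, Xb, masks = [], [], []
    ages = visits["age"].to_numpy(dtype=float)
    for k in params.markers:
        spec = design.specs[k]
        raw = visits[spec.visit_column].to_numpy(dtype=float)
        obs = np.isfinite(raw)
        y = np.where(obs, spec.apply_transform(np.where(obs, raw, 0.0)), np.nan)
        X = fixed_effects_matrix(ages, subject, spec, design.marker_basis)
        ys.append(y)
        Xb.append(X @ params.beta[k])
        masks.append(obs)
    return np.array(ys), np.array(Xb), np.array(masks)


def subject_loglik(
    subject,
    visits,
    design: ModelDesign,
    params: JointParams,
    n_ghq: int = 7,
    n_gl: int = 30,
    truncation: str = "conditional",
) -> float:
    """Marginal log-likelihood of one subject.

    Integrates the random intercepts out with adaptive Gauss-Hermite
    quadrature (n_ghq nodes per dimension), centered and scaled at the
    posterior mode/curvature of b.  Visits with an unobserved marker
    contribute the marginal density of the observed markers.

    truncation="conditional" uses the survival factor from entry age only;
    truncation="marginal" additionally divides by the marginal probability
    of being event-free from the left boundary age to entry.
    """
    K = len(params.markers)
    y, Xb, masks = _subject_arrays(subject, visits, design, params)
    Sb_inv = np.linalg.inv(params.Sigma_b)
    entry, exit_age = float(subject["entry_age"]), float(subject["exit_age"])
    delta = int(subject["event"])
    alpha = params.alpha_vec

    # quadratic form pieces: log N(y_j; mu_j + b_obs, Sigma_eps[obs, obs])
    A = np.zeros((K, K))
    h0 = np.zeros(K)
    const = 0.0
    for j in range(y.shape[1]):
        obs = masks[:, j]
        if not obs.any():
            continue
        S = params.Sigma_eps[np.ix_(obs, obs)]
        M = np.linalg.inv(S)
        r = (y[obs, j] - Xb[obs, j])
        Me = np.zeros((K, K))
        Me[np.ix_(obs, obs)] = M
        A += Me
        h0[obs] += M @ r
        const += -0.5 * (r @ M @ r) - 0.5 * (obs.sum() * LOG2PI + np.linalg.slogdet(S)[1])

    # survival pieces excluding alpha'b
    w = covariate_row(subject, [c for c in design.survival_covariates])
    gamma_vec = _gamma_vector(design, params)
    x_gl, w_gl = np.polynomial.legendre.leggauss(n_gl)
    mid, half = 0.5 * (entry + exit_age), 0.5 * (exit_age - entry)
    nodes = mid + half * x_gl
    c_nodes = (
        design.hazard_design(nodes) @ params.omega
        + w @ gamma_vec
        + alpha @ _subject_mu(nodes, subject, design, params, np.zeros(K))
    )
    Lam0 = half * (w_gl @ np.exp(c_nodes)) if exit_age > entry else 0.0
    cT = 0.0
    if delta:
        cT = float(
            design.hazard_design([exit_age])[0] @ params.omega
            + w @ gamma_vec
            + alpha @ _subject_mu([exit_age], subject, design, params, np.zeros(K))[:, 0]
        )

    def log_integrand(b):
        # b: (..., K)
        quad = -0.5 * np.einsum("...i,ij,...j->...", b, A + Sb_inv, b)
        lin = b @ h0
        u = b @ alpha
        surv = delta * u - np.exp(u) * Lam0
        return quad + lin + surv

    # posterior mode of b via Newton (log-concave)
    b = np.linalg.solve(A + Sb_inv, h0)
    Q = A + Sb_inv
    for _ in range(100):
        u = alpha @ b
        g = h0 - Q @ b + delta * alpha - np.exp(u) * Lam0 * alpha
        H = -Q - np.exp(u) * Lam0 * np.outer(alpha, alpha)
        step = np.linalg.solve(H, g)
        b_new = b - step
        if not np.isfinite(b_new).all():
            raise FloatingPointError(f"mode search diverged for subject {subject['id']!r}")
        if np.abs(b_new - b).max() < 1e-12:
            b = b_new
            break
        b = b_new
    else:
        if np.abs(step).max() > 1e-6:
            raise FloatingPointError(f"mode search did not converge for subject {subject['id']!r}")
    u = alpha @ b
    H = Q + np.exp(u) * Lam0 * np.outer(alpha, alpha)
    L = np.linalg.cholesky(np.linalg.inv(H))

    xh, wh = roots_hermite(n_ghq)
    grids = np.meshgrid(*([xh] * K), indexing="ij")
    Xstd = np.stack([g.ravel() for g in grids], axis=-1)  # (n_ghq^K, K)
    Wlog = np.log(np.prod(np.stack(np.meshgrid(*([wh] * K), indexing="ij")), axis=0)).ravel()
    B = b + np.sqrt(2.0) * Xstd @ L.T
    vals = log_integrand(B) + Wlog + (Xstd**2).sum(axis=1)
    log_int = (
        _logsumexp(vals)
        + 0.5 * K * np.log(2.0)
        + np.linalg.slogdet(L)[1]
    )

    ll = (
        const
        - 0.5 * (K * LOG2PI + np.linalg.slogdet(params.Sigma_b)[1])
        + delta * cT
        + log_int
    )
    if truncation == "marginal":
        ll -= _log_marginal_truncation(subject, design, params, n_ghq, n_gl)
    return float(ll)


def _log_marginal_truncation(subject, design, params, n_ghq, n_gl, age0=None):
    """log P(T > entry) marginalized over b (sensitivity-check variant)."""
    entry = float(subject["entry_age"])
    if age0 is None:
        age0 = design.hazard_basis.boundary_knots[0]
    if entry <= age0:
        return 0.0
    alpha = params.alpha_vec
    K = len(alpha)
    w = covariate_row(subject, [c for c in design.survival_covariates])
    x_gl, w_gl = np.polynomial.legendre.leggauss(n_gl)
    mid, half = 0.5 * (age0 + entry), 0.5 * (entry - age0)
    nodes = mid + half * x_gl
    c_nodes = (
        design.hazard_design(nodes) @ params.omega
        + w @ _gamma_vector(design, params)
        + alpha @ _subject_mu(nodes, subject, design, params, np.zeros(K))
    )
    Lam0 = half * (w_gl @ np.exp(c_nodes))
    s2 = float(alpha @ params.Sigma_b @ alpha)
    if s2 <= 0:
        return -Lam0
    xh, wh = roots_hermite(max(n_ghq, 15))
    u = np.sqrt(2.0 * s2) * xh
    return float(_logsumexp(-np.exp(u) * Lam0 + np.log(wh)) - 0.5 * np.log(np.pi))


def _logsumexp(v):
    m = np.max(v, axis=-1, keepdims=True)
    return (m + np.log(np.sum(np.exp(v - m), axis=-1, keepdims=True)))[..., 0]


# --------------------------------------------------------------------------
# vectorized cohort likelihood
# --------------------------------------------------------------------------


class CohortLikelihood:
    """Marginal log-likelihood of a cohort, vectorized across subjects.

    All parameter-independent design quantities (per-subject, per-missingness-
    pattern sufficient statistics of the longitudinal data; Gauss-Legendre node
    designs for the cumulative hazard) are precomputed once, so each likelihood
    evaluation is a handful of batched linear-algebra operations.

    The random intercepts enter the survival factor only through u = alpha'b,
    so after completing the Gaussian square the K-dimensional integral reduces
    exactly to a 1-D integral over u, evaluated with adaptive Gauss-Hermite
    quadrature (mode + curvature rescaling, `n_ghq` nodes).
    """

    def __init__(
        self,
        subjects,
        visits,
        design: ModelDesign,
        n_ghq: int = 7,
        n_gl: int = 21,
        truncation: str = "conditional",
    ):
        self.design = design
        self.markers = design.markers
        self.n_ghq = int(n_ghq)
        self.n_gl = int(n_gl)
        self.truncation = truncation
        self.subjects = subjects.reset_index(drop=True)
        self.n = len(self.subjects)
        K = self.K = len(self.markers)

        ids = self.subjects["id"].to_numpy()
        id_to_row = {s: i for i, s in enumerate(ids)}
        v = visits[visits["id"].isin(id_to_row)].reset_index(drop=True)
        self.subj_of_visit = v["id"].map(id_to_row).to_numpy()
        ages = v["age"].to_numpy(dtype=float)
        V = len(v)

        # stacked per-visit responses and design matrices per marker
        NS = design.marker_spline(ages)  # (V, df)
        self.p_k = {}
        Y = np.zeros((V, K))
        Xs = {}
        obs = np.zeros((V, K), dtype=bool)
        for j, k in enumerate(self.markers):
            spec = design.specs[k]
            raw = v[spec.visit_column].to_numpy(dtype=float)
            ok = np.isfinite(raw)
            obs[:, j] = ok
            Y[ok, j] = spec.apply_transform(raw[ok])
            Wk, _ = covariate_matrix(self.subjects, spec.covariates)
            X = np.concatenate(
                [np.ones((V, 1)), NS, Wk[self.subj_of_visit]], axis=1
            )
            X[~ok] = 0.0
            Xs[k] = X
            self.p_k[k] = X.shape[1]
        Y[~obs] = 0.0

        # group visits by missingness pattern; accumulate per-subject sums
        pat_codes = obs @ (1 << np.arange(K))
        self.patterns = []
        for code in np.unique(pat_codes):
            mask = pat_codes == code
            rows = np.flatnonzero(mask)
            pobs = np.array([(code >> j) & 1 for j in range(K)], dtype=bool)
            si = self.subj_of_visit[rows]
            n = self.n
            count = np.bincount(si, minlength=n).astype(float)
            Sy = np.zeros((n, K))
            Syy = np.zeros((n, K, K))
            np.add.at(Sy, si, Y[rows])
            np.add.at(Syy, si, np.einsum("vi,vj->vij", Y[rows], Y[rows]))
            SX = {}
            Sxy = {}
            Sxx = {}
            for a, ka in enumerate(self.markers):
                if not pobs[a]:
                    continue
                Xa = Xs[ka][rows]
                acc = np.zeros((n, self.p_k[ka]))
                np.add.at(acc, si, Xa)
                SX[ka] = acc
                for bb, kb in enumerate(self.markers):
                    if not pobs[bb]:
                        continue
                    acc2 = np.zeros((n, self.p_k[kb]))
                    np.add.at(acc2, si, Y[rows][:, a, None] * Xs[kb][rows])
                    Sxy[(ka, kb)] = acc2  # sum over visits of y_a * x_b
                    if a <= bb:
                        acc3 = np.zeros((n, self.p_k[ka], self.p_k[kb]))
                        np.add.at(acc3, si, np.einsum("vp,vq->vpq", Xa, Xs[kb][rows]))
                        Sxx[(ka, kb)] = acc3
            # cohort totals: the quadratic forms only enter the summed
            # likelihood, so they collapse across subjects
            self.patterns.append(
                dict(
                    obs=pobs, count=count, Sy=Sy, Syy=Syy, SX=SX, Sxy=Sxy, Sxx=Sxx,
                    n_visits=float(len(rows)),
                    Syy_tot=Syy.sum(axis=0),
                    Sxy_tot={key: vv.sum(axis=0) for key, vv in Sxy.items()},
                    Sxx_tot={key: vv.sum(axis=0) for key, vv in Sxx.items()},
                )
            )

        # survival designs
        self.entry = self.subjects["entry_age"].to_numpy(dtype=float)
        self.exit = self.subjects["exit_age"].to_numpy(dtype=float)
        self.delta = self.subjects["event"].to_numpy(dtype=int)
        self.w_surv, self.w_names = covariate_matrix(
            self.subjects, design.survival_covariates
        )
        x_gl, w_gl = np.polynomial.legendre.leggauss(self.n_gl)
        self.gl_w = w_gl
        mid = 0.5 * (self.entry + self.exit)
        self.gl_half = 0.5 * (self.exit - self.entry)
        nodes = mid[:, None] + self.gl_half[:, None] * x_gl[None, :]  # (n, Q)
        self.S0n = design.hazard_design(nodes)  # (n, Q, 1+dfh)
        self.NSn = design.marker_spline(nodes)  # (n, Q, df)
        self.S0T = design.hazard_design(self.exit)  # (n, 1+dfh)
        self.NST = design.marker_spline(self.exit)  # (n, df)
        self.Wm = {
            k: covariate_matrix(self.subjects, design.specs[k].covariates)[0]
            for k in self.markers
        }
        if truncation == "marginal":
            lo = design.hazard_basis.boundary_knots[0]
            e_half = 0.5 * np.maximum(self.entry - lo, 0.0)
            e_nodes = (lo + e_half)[:, None] + e_half[:, None] * x_gl[None, :]
            self.e_half = e_half
            self.S0e = design.hazard_design(e_nodes)
            self.NSe = design.marker_spline(e_nodes)

        self.xh, self.wh = roots_hermite(self.n_ghq)
        self.total_visits = V
        self.total_events = int(self.delta.sum())
        # kept for moment-based starting values
        self._Y, self._Xs, self._obs = Y, Xs, obs

    # -- parameter-dependent pieces ------------------------------------

    def loglik(self, params: JointParams, include_survival: bool = True) -> float:
        ll, const = self._loglik_core(params, include_survival, per_subject=False)
        return float(ll.sum() + const)

    def loglik_by_subject(self, params: JointParams, include_survival: bool = True):
        ll, _ = self._loglik_core(params, include_survival, per_subject=True)
        return ll

    def _loglik_core(self, params: JointParams, include_survival: bool, per_subject: bool):
        n, K = self.n, self.K
        Sb_inv = np.linalg.inv(params.Sigma_b)
        A = np.zeros((n, K, K))
        h = np.zeros((n, K))
        const = np.zeros(n) if per_subject else 0.0
        for pat in self.patterns:
            pobs = pat["obs"]
            S = params.Sigma_eps[np.ix_(pobs, pobs)]
            M = np.linalg.inv(S)
            logdetS = np.linalg.slogdet(S)[1]
            Me = np.zeros((K, K))
            Me[np.ix_(pobs, pobs)] = M
            A += pat["count"][:, None, None] * Me
            # residual sums per marker
            sr = np.zeros((n, K))
            for a, ka in enumerate(self.markers):
                if pobs[a]:
                    sr[:, a] = pat["Sy"][:, a] - pat["SX"][ka] @ params.beta[ka]
            h += sr @ Me
            # sum over visits of r' M r; collapses across subjects unless the
            # per-subject breakdown is requested
            quad = np.zeros(n) if per_subject else 0.0
            for a, ka in enumerate(self.markers):
                if not pobs[a]:
                    continue
                for bb, kb in enumerate(self.markers):
                    if not pobs[bb]:
                        continue
                    lo_pair = (ka, kb) if a <= bb else (kb, ka)
                    blo, bhi = (
                        (params.beta[ka], params.beta[kb])
                        if a <= bb
                        else (params.beta[kb], params.beta[ka])
                    )
                    if per_subject:
                        bxb = np.einsum("p,npq,q->n", blo, pat["Sxx"][lo_pair], bhi)
                        rr = (
                            pat["Syy"][:, a, bb]
                            - pat["Sxy"][(ka, kb)] @ params.beta[kb]
                            - pat["Sxy"][(kb, ka)] @ params.beta[ka]
                            + bxb
                        )
                    else:
                        rr = (
                            pat["Syy_tot"][a, bb]
                            - pat["Sxy_tot"][(ka, kb)] @ params.beta[kb]
                            - pat["Sxy_tot"][(kb, ka)] @ params.beta[ka]
                            + blo @ pat["Sxx_tot"][lo_pair] @ bhi
                        )
                    quad += Me[a, bb] * rr
            counts = pat["count"] if per_subject else pat["n_visits"]
            const += -0.5 * quad - 0.5 * counts * (pobs.sum() * LOG2PI + logdetS)

        Q = A + Sb_inv
        Qinv, logdetQ = _batch_inv_logdet(Q)
        m = np.einsum("nij,nj->ni", Qinv, h)
        hm = np.einsum("ni,ni->n", h, m)
        logdetSb = np.linalg.slogdet(params.Sigma_b)[1]
        # per-subject terms; `const` stays a cohort scalar in the fast path
        ll = -0.5 * logdetSb - 0.5 * logdetQ + 0.5 * hm
        if per_subject:
            ll = ll + const
            const = 0.0

        if not include_survival:
            return ll, const

        alpha = params.alpha_vec
        gamma_vec = np.array([params.gamma.get(nm, 0.0) for nm in self.w_names])
        wg = self.w_surv @ gamma_vec
        c_nodes = self.S0n @ params.omega + wg[:, None]
        cT = self.S0T @ params.omega + wg
        for j, k in enumerate(self.markers):
            beta = params.beta[k]
            df = self.NSn.shape[-1]
            mu_n = beta[0] + self.NSn @ beta[1 : 1 + df] + (self.Wm[k] @ beta[1 + df :])[:, None]
            mu_T = beta[0] + self.NST @ beta[1 : 1 + df] + self.Wm[k] @ beta[1 + df :]
            c_nodes = c_nodes + alpha[j] * mu_n
            cT = cT + alpha[j] * mu_T
        if not np.isfinite(c_nodes).all():
            raise FloatingPointError("non-finite hazard linear predictor")
        Lam0 = self.gl_half * (np.exp(c_nodes) @ self.gl_w)

        mu_u = m @ alpha
        s2_u = np.maximum(np.einsum("i,nij,j->n", alpha, Qinv, alpha), 1e-12)
        I = _log_E_exp_survival(self.delta, Lam0, mu_u, s2_u, self.xh, self.wh)
        ll = ll + self.delta * cT + I

        if self.truncation == "marginal":
            c_e = self.S0e @ params.omega + wg[:, None]
            for j, k in enumerate(self.markers):
                beta = params.beta[k]
                df = self.NSe.shape[-1]
                c_e = c_e + alpha[j] * (
                    beta[0] + self.NSe @ beta[1 : 1 + df] + (self.Wm[k] @ beta[1 + df :])[:, None]
                )
            Lam0e = self.e_half * (np.exp(c_e) @ self.gl_w)
            s2_prior = max(float(alpha @ params.Sigma_b @ alpha), 1e-12)
            corr = _log_E_exp_survival(
                np.zeros(n, dtype=int), Lam0e, np.zeros(n), np.full(n, s2_prior),
                self.xh, self.wh,
            )
            ll = ll - corr
        return ll, const

    # -- analytic gradient (fast path for fitting) ---------------------

    def loglik_and_grad(self, params: JointParams, include_survival: bool = True):
        """Total log-likelihood and its gradient in the packed parameter
        space (log-Cholesky covariances), derived analytically.

        Only the conditional-truncation likelihood is supported; the marginal
        variant falls back to finite differences in the fitter.
        """
        if self.truncation == "marginal":
            raise NotImplementedError("analytic gradient requires conditional truncation")
        tf = self._get_transform()
        n, K = self.n, self.K
        Sigma_b = params.Sigma_b
        Sb_inv = np.linalg.inv(Sigma_b)
        L_b = np.linalg.cholesky(Sigma_b)
        L_eps = np.linalg.cholesky(params.Sigma_eps)

        A = np.zeros((n, K, K))
        h = np.zeros((n, K))
        const = 0.0
        pat_cache = []
        for pat in self.patterns:
            pobs = pat["obs"]
            S = params.Sigma_eps[np.ix_(pobs, pobs)]
            M = np.linalg.inv(S)
            logdetS = np.linalg.slogdet(S)[1]
            Me = np.zeros((K, K))
            Me[np.ix_(pobs, pobs)] = M
            A += pat["count"][:, None, None] * Me
            sr = np.zeros((n, K))
            for a, ka in enumerate(self.markers):
                if pobs[a]:
                    sr[:, a] = pat["Sy"][:, a] - pat["SX"][ka] @ params.beta[ka]
            h += sr @ Me
            # cohort-total residual cross-product matrix R[a,b] = sum_j r_a r_b
            R = np.zeros((K, K))
            for a, ka in enumerate(self.markers):
                if not pobs[a]:
                    continue
                for b, kb in enumerate(self.markers):
                    if not pobs[b]:
                        continue
                    lo_pair = (ka, kb) if a <= b else (kb, ka)
                    blo, bhi = (
                        (params.beta[ka], params.beta[kb])
                        if a <= b
                        else (params.beta[kb], params.beta[ka])
                    )
                    R[a, b] = (
                        pat["Syy_tot"][a, b]
                        - pat["Sxy_tot"][(ka, kb)] @ params.beta[kb]
                        - pat["Sxy_tot"][(kb, ka)] @ params.beta[ka]
                        + blo @ pat["Sxx_tot"][lo_pair] @ bhi
                    )
            quad = float(np.sum(Me * R))
            const += -0.5 * quad - 0.5 * pat["n_visits"] * (pobs.sum() * LOG2PI + logdetS)
            pat_cache.append(dict(pat=pat, M=M, Me=Me, S=S, sr=sr, R=R))

        Q = A + Sb_inv
        Qinv, logdetQ = _batch_inv_logdet(Q)
        m = np.einsum("nij,nj->ni", Qinv, h)
        hm = np.einsum("ni,ni->n", h, m)
        logdetSb = np.linalg.slogdet(Sigma_b)[1]
        ll = const + np.sum(-0.5 * logdetSb - 0.5 * logdetQ + 0.5 * hm)

        grad = np.zeros(tf.n_params)
        if include_survival:
            alpha = params.alpha_vec
            gamma_vec = np.array([params.gamma.get(nm, 0.0) for nm in self.w_names])
            wg = self.w_surv @ gamma_vec
            c_nodes = self.S0n @ params.omega + wg[:, None]
            cT = self.S0T @ params.omega + wg
            mu_n, mu_T = {}, {}
            df = self.NSn.shape[-1]
            for j, k in enumerate(self.markers):
                beta = params.beta[k]
                wk = self.Wm[k] @ beta[1 + df :]
                mu_n[k] = beta[0] + self.NSn @ beta[1 : 1 + df] + wk[:, None]
                mu_T[k] = beta[0] + self.NST @ beta[1 : 1 + df] + wk
                c_nodes = c_nodes + alpha[j] * mu_n[k]
                cT = cT + alpha[j] * mu_T[k]
            if not np.isfinite(c_nodes).all():
                raise FloatingPointError("non-finite hazard linear predictor")
            exp_c = np.exp(c_nodes)
            Lam0 = self.gl_half * (exp_c @ self.gl_w)
            mu_u = m @ alpha
            aq = np.einsum("nij,j->ni", Qinv, alpha)
            s2_u = np.maximum(aq @ alpha, 1e-12)
            I, dIdmu, dIds2, dIdLam0 = _log_E_exp_survival_derivs(
                self.delta, Lam0, mu_u, s2_u, self.xh, self.wh
            )
            delta = self.delta.astype(float)
            ll += float(np.sum(delta * cT + I))
            # weights for d Lam0 / d(linear predictor at the GL nodes)
            wgt = (dIdLam0 * self.gl_half)[:, None] * self.gl_w[None, :] * exp_c
            wgt_row = wgt.sum(axis=1)

            grad[tf.blocks["omega"]] = delta @ self.S0T + np.einsum(
                "nq,nqp->p", wgt, self.S0n
            )
            grad[tf.blocks["gamma"]] = (delta + dIdLam0 * Lam0) @ self.w_surv
            galpha = np.empty(K)
            for j, k in enumerate(self.markers):
                galpha[j] = (
                    delta @ mu_T[k]
                    + np.sum(wgt * mu_n[k])
                    + dIdmu @ m[:, j]
                    + 2.0 * (dIds2 @ aq[:, j])
                )
            grad[tf.blocks["alpha"]] = galpha
            dlldh = m + dIdmu[:, None] * aq
            dlldQ = (
                -0.5 * Qinv
                - 0.5 * np.einsum("ni,nj->nij", m, m)
                - 0.5
                * dIdmu[:, None, None]
                * (np.einsum("ni,nj->nij", aq, m) + np.einsum("ni,nj->nij", m, aq))
                - dIds2[:, None, None] * np.einsum("ni,nj->nij", aq, aq)
            )
        else:
            dlldh = m
            dlldQ = -0.5 * Qinv - 0.5 * np.einsum("ni,nj->nij", m, m)

        # beta blocks
        for j, k in enumerate(self.markers):
            g = np.zeros(tf.blocks[f"beta_{k}"].stop - tf.blocks[f"beta_{k}"].start)
            for cache in pat_cache:
                pat, Me, sr = cache["pat"], cache["Me"], cache["sr"]
                if not pat["obs"][j]:
                    continue
                # residual quadratic (cohort totals)
                for a, ka in enumerate(self.markers):
                    if not pat["obs"][a]:
                        continue
                    t_ak = pat["Sxy_tot"][(ka, k)].copy()
                    if a <= j:
                        t_ak -= params.beta[ka] @ pat["Sxx_tot"][(ka, k)]
                    else:
                        t_ak -= pat["Sxx_tot"][(k, ka)] @ params.beta[ka]
                    g += Me[j, a] * t_ak
                # posterior-mean pathway through h
                coef = dlldh @ Me  # (n, K)
                g -= coef[:, j] @ pat["SX"][k]
            if include_survival:
                ak = params.alpha_vec[j]
                gs = np.concatenate(
                    [
                        [delta.sum() + wgt.sum()],
                        delta @ self.NST + np.einsum("nq,nqd->d", wgt, self.NSn),
                        (delta + wgt_row) @ self.Wm[k],
                    ]
                )
                g += ak * gs
            grad[tf.blocks[f"beta_{k}"]] = g

        # random-intercept covariance (log-Cholesky chain)
        Dq = dlldQ.sum(axis=0)
        D_Sb = -Sb_inv @ Dq @ Sb_inv - 0.5 * self.n * Sb_inv
        Gb = 2.0 * D_Sb @ L_b
        grad[tf.blocks["chol_b"]] = [
            Gb[i, jj] * (L_b[i, i] if i == jj else 1.0) for i, jj in tf.tri
        ]

        # residual covariance (per missingness pattern, then chain)
        D_S_full = np.zeros((K, K))
        for cache in pat_cache:
            pat, M, sr, R = cache["pat"], cache["M"], cache["sr"], cache["R"]
            pobs = pat["obs"]
            block = np.ix_(pobs, pobs)
            D_M = 0.5 * pat["n_visits"] * cache["S"] - 0.5 * R[block]
            D_M = D_M + (pat["count"][:, None, None] * dlldQ).sum(axis=0)[block]
            Dh = np.einsum("ni,nj->ij", dlldh[:, pobs], sr[:, pobs])
            D_M = D_M + 0.5 * (Dh + Dh.T)
            D_S_full[block] += -M @ D_M @ M
        Ge = 2.0 * D_S_full @ L_eps
        grad[tf.blocks["chol_eps"]] = [
            Ge[i, jj] * (L_eps[i, i] if i == jj else 1.0) for i, jj in tf.tri
        ]
        return float(ll), grad

    def _get_transform(self):
        if not hasattr(self, "_tf") or self._tf is None:
            self._tf = ParamTransform(self.design)
        return self._tf


def _batch_inv_logdet(Q: np.ndarray):
    """Inverse and log-determinant of a stack of SPD 2x2 / 3x3 matrices."""
    K = Q.shape[-1]
    if K == 2:
        a, b, d = Q[:, 0, 0], Q[:, 0, 1], Q[:, 1, 1]
        det = a * d - b * b
        inv = np.empty_like(Q)
        inv[:, 0, 0] = d
        inv[:, 1, 1] = a
        inv[:, 0, 1] = inv[:, 1, 0] = -b
        inv /= det[:, None, None]
        return inv, np.log(det)
    if K == 3:
        a, b, c = Q[:, 0, 0], Q[:, 0, 1], Q[:, 0, 2]
        d, e, f = Q[:, 1, 1], Q[:, 1, 2], Q[:, 2, 2]
        A = d * f - e * e
        B = c * e - b * f
        C = b * e - c * d
        det = a * A + b * B + c * C
        inv = np.empty_like(Q)
        inv[:, 0, 0] = A
        inv[:, 0, 1] = inv[:, 1, 0] = B
        inv[:, 0, 2] = inv[:, 2, 0] = C
        inv[:, 1, 1] = a * f - c * c
        inv[:, 1, 2] = inv[:, 2, 1] = b * c - a * e
        inv[:, 2, 2] = a * d - b * b
        inv /= det[:, None, None]
        return inv, np.log(det)
    sign, logdet = np.linalg.slogdet(Q)
    return np.linalg.inv(Q), logdet


def _log_E_exp_survival_derivs(delta, Lam0, mu, s2, xh, wh):
    """As `_log_E_exp_survival`, also returning the derivatives of the
    integral with respect to (mu, s2, Lam0) via posterior-weighted moments."""
    delta = np.asarray(delta, dtype=float)
    u = mu.copy()
    for _ in range(50):
        eu = np.exp(u) * Lam0
        g1 = delta - eu - (u - mu) / s2
        g2 = -eu - 1.0 / s2
        step = g1 / g2
        np.clip(step, -3.0, 3.0, out=step)
        u = u - step
        if np.abs(step).max() < 1e-12:
            break
    s_hat = 1.0 / np.sqrt(np.exp(u) * Lam0 + 1.0 / s2)
    nodes = u[:, None] + np.sqrt(2.0) * s_hat[:, None] * xh[None, :]
    g = (
        delta[:, None] * nodes
        - np.exp(nodes) * Lam0[:, None]
        - 0.5 * (nodes - mu[:, None]) ** 2 / s2[:, None]
    )
    vals = g + np.log(wh)[None, :] + xh[None, :] ** 2
    lse = _logsumexp(vals)
    I = lse + np.log(np.sqrt(2.0) * s_hat) - 0.5 * np.log(2.0 * np.pi * s2)
    p = np.exp(vals - lse[:, None])  # posterior node weights
    z = nodes - mu[:, None]
    dmu = np.sum(p * z, axis=1) / s2
    ds2 = np.sum(p * (z**2 / s2[:, None] - 1.0), axis=1) / (2.0 * s2)
    dLam0 = -np.sum(p * np.exp(nodes), axis=1)
    return I, dmu, ds2, dLam0


def _log_E_exp_survival(delta, Lam0, mu, s2, xh, wh):
    """log E[exp(delta*u - exp(u)*Lam0)] for u ~ N(mu, s2), adaptive GH.

    Vectorized over subjects; the integrand is log-concave in u, so a Newton
    search from the Gaussian mean finds the mode, and Gauss-Hermite nodes are
    recentred and rescaled there.
    """
    delta = np.asarray(delta, dtype=float)
    u = mu.copy()
    for _ in range(50):
        eu = np.exp(u) * Lam0
        g1 = delta - eu - (u - mu) / s2
        g2 = -eu - 1.0 / s2
        step = g1 / g2
        np.clip(step, -3.0, 3.0, out=step)
        u = u - step
        if np.abs(step).max() < 1e-12:
            break
    s_hat = 1.0 / np.sqrt(np.exp(u) * Lam0 + 1.0 / s2)
    nodes = u[:, None] + np.sqrt(2.0) * s_hat[:, None] * xh[None, :]
    g = (
        delta[:, None] * nodes
        - np.exp(nodes) * Lam0[:, None]
        - 0.5 * (nodes - mu[:, None]) ** 2 / s2[:, None]
    )
    vals = g + np.log(wh)[None, :] + xh[None, :] ** 2
    return (
        _logsumexp(vals)
        + np.log(np.sqrt(2.0) * s_hat)
        - 0.5 * np.log(2.0 * np.pi * s2)
    )


# --------------------------------------------------------------------------
# parameter vector <-> JointParams (log-Cholesky for the covariances)
# --------------------------------------------------------------------------


class ParamTransform:
    """Bijection between a flat parameter vector and `JointParams`.

    Covariance matrices are parameterized by their Cholesky factors with
    logged diagonals, which keeps every vector in R^p a valid positive
    definite parameter set.
    """

    def __init__(self, design: ModelDesign):
        self.design = design
        self.markers = design.markers
        K = len(self.markers)
        self.names: list[str] = []
        self.blocks: dict[str, slice] = {}

        def add(block, names):
            start = len(self.names)
            self.names += names
            self.blocks[block] = slice(start, len(self.names))

        for k in self.markers:
            add(f"beta_{k}", design.specs[k].fixed_effect_names(design.marker_basis))
        tri = [(i, j) for i in range(K) for j in range(i + 1)]
        self.tri = tri
        add("chol_b", [f"Sigma_b:L{i}{j}" for i, j in tri])
        add("chol_eps", [f"Sigma_eps:L{i}{j}" for i, j in tri])
        add("omega", ["haz:intercept"] + [f"haz:ns{j+1}" for j in range(design.hazard_basis.df)])
        _, wnames = covariate_matrix_names(design)
        add("gamma", [f"surv:{nm}" for nm in wnames])
        add("alpha", [f"alpha:{k}" for k in self.markers])
        self.n_params = len(self.names)
        self.w_names = wnames

    def _chol_to_vec(self, S):
        L = np.linalg.cholesky(S)
        return np.array([np.log(L[i, j]) if i == j else L[i, j] for i, j in self.tri])

    def _vec_to_cov(self, v):
        K = len(self.markers)
        L = np.zeros((K, K))
        for val, (i, j) in zip(v, self.tri):
            L[i, j] = np.exp(val) if i == j else val
        return L @ L.T

    def pack(self, params: JointParams) -> np.ndarray:
        theta = np.empty(self.n_params)
        for k in self.markers:
            theta[self.blocks[f"beta_{k}"]] = params.beta[k]
        theta[self.blocks["chol_b"]] = self._chol_to_vec(params.Sigma_b)
        theta[self.blocks["chol_eps"]] = self._chol_to_vec(params.Sigma_eps)
        theta[self.blocks["omega"]] = params.omega
        theta[self.blocks["gamma"]] = [params.gamma.get(nm, 0.0) for nm in self.w_names]
        theta[self.blocks["alpha"]] = params.alpha_vec
        return theta

    def unpack(self, theta: np.ndarray) -> JointParams:
        beta = {k: np.array(theta[self.blocks[f"beta_{k}"]]) for k in self.markers}
        return JointParams(
            markers=self.markers,
            beta=beta,
            Sigma_b=self._vec_to_cov(theta[self.blocks["chol_b"]]),
            Sigma_eps=self._vec_to_cov(theta[self.blocks["chol_eps"]]),
            omega=np.array(theta[self.blocks["omega"]]),
            gamma=dict(zip(self.w_names, theta[self.blocks["gamma"]])),
            alpha=dict(zip(self.markers, theta[self.blocks["alpha"]])),
        )


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, covariance and diagnostics of one model fit."""

    model: str
    param_names: list
    theta: np.ndarray
    free: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_inf: float
    vcov: np.ndarray | None = None
    hr_rows: list = field(default_factory=list)
    knots: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    transform: ParamTransform | None = field(default=None, repr=False)

    @property
    def estimates(self) -> dict:
        return dict(zip(self.param_names, self.theta))

    def params(self) -> JointParams:
        return self.transform.unpack(self.theta)

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        if self.vcov is None or not np.isfinite(self.vcov[i, i]):
            return np.nan
        return float(np.sqrt(self.vcov[i, i]))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "grad_inf": float(self.grad_inf),
            "hr_rows": self.hr_rows,
            "knots": self.knots,
            "options": self.options,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _pd_clip(S, floor=1e-4):
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, floor * max(vals.max(), 1.0))
    return vecs @ np.diag(vals) @ vecs.T


def _moment_start(cl: CohortLikelihood) -> JointParams:
    """Cheap OLS / variance-component starting values."""
    K, n = cl.K, cl.n
    Y, obs = cl._Y, cl._obs
    beta = {}
    resid = np.full(Y.shape, np.nan)
    for j, k in enumerate(cl.markers):
        X = cl._Xs[k][obs[:, j]]
        y = Y[obs[:, j], j]
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta[k] = bhat
        resid[obs[:, j], j] = y - X @ bhat
    si = cl.subj_of_visit
    counts = np.zeros((n, K))
    sums = np.zeros((n, K))
    np.add.at(counts, si, obs.astype(float))
    np.add.at(sums, si, np.nan_to_num(resid))
    with np.errstate(invalid="ignore"):
        rbar = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    dev = resid - rbar[si]
    Sigma_eps = np.empty((K, K))
    Sigma_b = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            both = np.isfinite(dev[:, a]) & np.isfinite(dev[:, b])
            Sigma_eps[a, b] = (
                np.mean(dev[both, a] * dev[both, b]) * 1.5 if both.any() else 0.0
            )
            bothm = np.isfinite(rbar[:, a]) & np.isfinite(rbar[:, b])
            Sigma_b[a, b] = np.mean(rbar[bothm, a] * rbar[bothm, b]) if bothm.any() else 0.0
    Sigma_eps = _pd_clip(Sigma_eps, 1e-3)
    mean_inv_n = np.mean(1.0 / np.maximum(counts[:, 0], 1.0))
    Sigma_b = _pd_clip(Sigma_b - mean_inv_n * Sigma_eps, 1e-3)
    persontime = float(np.sum(cl.exit - cl.entry))
    rate = max(cl.total_events, 0.5) / max(persontime, 1e-8)
    omega = np.zeros(1 + cl.design.hazard_basis.df)
    omega[0] = np.log(rate)
    return JointParams(
        markers=cl.markers,
        beta=beta,
        Sigma_b=Sigma_b,
        Sigma_eps=Sigma_eps,
        omega=omega,
        gamma={nm: 0.0 for nm in cl.w_names},
        alpha={k: 0.0 for k in cl.markers},
    )


def _optimize_subset(cl, tf, theta, free_mask, include_survival, maxiter, gtol=1e-3):
    theta = theta.copy()
    idx = np.flatnonzero(free_mask)
    if idx.size == 0:
        return theta, None
    use_grad = cl.truncation != "marginal"

    if use_grad:

        def nll(x):
            th = theta.copy()
            th[idx] = x
            try:
                ll, g = cl.loglik_and_grad(tf.unpack(th), include_survival=include_survival)
                return -ll, -g[idx]
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                return 1e12, np.zeros(idx.size)

    else:

        def nll(x):
            th = theta.copy()
            th[idx] = x
            try:
                return -cl.loglik(tf.unpack(th), include_survival=include_survival)
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                return 1e12

    res = optimize.minimize(
        nll,
        theta[idx],
        jac=use_grad or None,
        method="L-BFGS-B",
        options=dict(maxiter=maxiter, ftol=1e-11, gtol=gtol, maxcor=25),
    )
    theta[idx] = res.x
    return theta, res


def fit_joint_model(
    subjects,
    visits,
    specs,
    design: ModelDesign | None = None,
    *,
    start: JointParams | None = None,
    fixed: tuple = (),
    n_ghq: int = 7,
    n_gl: int = 21,
    truncation: str = "conditional",
    compute_vcov: bool = True,
    maxiter: tuple = (300, 100, 500),
    model_label: str | None = None,
) -> FitResult:
    """Maximum marginal likelihood fit of the K-marker joint model.

    Two-stage start: (1) the multivariate mixed model ignoring survival,
    (2) the spline-hazard survival submodel at alpha = 0; then all parameters
    are released.  `fixed` names parameters held at their starting values
    (useful for nesting checks).  Non-convergence is flagged, never silent.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("joint model needs at least 2 markers")
    if design is None:
        design = ModelDesign.from_data(subjects, visits, specs)
    cl = CohortLikelihood(
        subjects, visits, design, n_ghq=n_ghq, n_gl=n_gl, truncation=truncation
    )
    tf = ParamTransform(design)
    theta = tf.pack(start if start is not None else _moment_start(cl))
    fixed_mask = np.zeros(tf.n_params, dtype=bool)
    for nm in fixed:
        if nm not in tf.names:
            raise ValueError(f"unknown fixed parameter {nm!r}")
        fixed_mask[tf.names.index(nm)] = True

    is_long = np.zeros(tf.n_params, dtype=bool)
    for k in design.markers:
        is_long[tf.blocks[f"beta_{k}"]] = True
    is_long[tf.blocks["chol_b"]] = True
    is_long[tf.blocks["chol_eps"]] = True
    is_surv = np.zeros(tf.n_params, dtype=bool)
    is_surv[tf.blocks["omega"]] = True
    is_surv[tf.blocks["gamma"]] = True

    n_iter = 0
    if start is None:
        theta, res1 = _optimize_subset(
            cl, tf, theta, is_long & ~fixed_mask, False, maxiter[0], gtol=1e-2
        )
        n_iter += getattr(res1, "nit", 0)
        theta, res2 = _optimize_subset(
            cl, tf, theta, is_surv & ~fixed_mask, True, maxiter[1], gtol=1e-2
        )
        n_iter += getattr(res2, "nit", 0)
    theta, res = _optimize_subset(cl, tf, theta, ~fixed_mask, True, maxiter[2])
    n_iter += getattr(res, "nit", 0)
    grad_inf = float(np.abs(res.jac).max()) if res is not None else np.nan
    converged = bool(res is not None and res.success)
    loglik = cl.loglik(tf.unpack(theta))

    vcov = None
    if compute_vcov:
        vcov = _numeric_vcov(cl, tf, theta, ~fixed_mask)

    fit = FitResult(
        model=model_label or ("joint3" if "bmi" in design.markers else "joint2"),
        param_names=list(tf.names),
        theta=theta,
        free=~fixed_mask,
        loglik=float(loglik),
        converged=converged,
        n_iter=int(n_iter),
        grad_inf=grad_inf,
        vcov=vcov,
        knots={
            "marker_basis": design.marker_basis.to_dict(),
            "hazard_basis": design.hazard_basis.to_dict(),
        },
        options=dict(n_ghq=n_ghq, n_gl=n_gl, truncation=truncation, maxiter=list(maxiter)),
        transform=tf,
    )
    wald_inference(fit)
    return fit


def _numeric_vcov(cl, tf, theta, free_mask):
    """Observed-information covariance from a central-difference Hessian."""
    idx = np.flatnonzero(free_mask)
    p = idx.size

    x0 = theta[idx]
    h = 1e-4 * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    if cl.truncation != "marginal":
        # central differences of the analytic gradient
        def g(x):
            th = theta.copy()
            th[idx] = x
            return cl.loglik_and_grad(tf.unpack(th))[1][idx]

        for i in range(p):
            ei = np.zeros(p)
            ei[i] = h[i]
            H[:, i] = (g(x0 + ei) - g(x0 - ei)) / (2 * h[i])
        H = 0.5 * (H + H.T)
    else:

        def f(x):
            th = theta.copy()
            th[idx] = x
            return cl.loglik(tf.unpack(th))

        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    info = -H
    try:
        cov_free = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(info)
    vcov = np.full((tf.n_params, tf.n_params), np.nan)
    vcov[np.ix_(idx, idx)] = cov_free
    return vcov


# --------------------------------------------------------------------------
# Wald inference
# --------------------------------------------------------------------------


def wald_inference(fit: FitResult, terms=None, level: float = 0.95) -> list:
    """Hazard-ratio rows (HR, CI, p) for the survival-scale coefficients.

    By default covers every association coefficient and survival covariate
    effect; HR = exp(estimate), CI = exp(estimate +/- z * SE), two-sided
    normal p-value.
    """
    if terms is None:
        terms = [nm for nm in fit.param_names if nm.startswith(("alpha:", "surv:"))]
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for nm in terms:
        est = fit.estimates[nm]
        se = fit.se(nm)
        if np.isfinite(se) and se > 0:
            p = 2 * stats.norm.sf(abs(est) / se)
            lo = np.exp(np.clip(est - z * se, -700, 700))
            hi = np.exp(np.clip(est + z * se, -700, 700))
        else:
            p, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            dict(term=nm, estimate=float(est), se=float(se), HR=float(np.exp(est)),
                 ci_low=float(lo), ci_high=float(hi), p=float(p))
        )
    fit.hr_rows = rows
    return rows


def joint_wald_test(fit: FitResult, terms) -> dict:
    """Joint Wald chi-square that the named coefficients are all zero."""
    if fit.vcov is None:
        raise ValueError("fit has no covariance matrix; rerun with compute_vcov=True")
    idx = [fit.param_names.index(t) for t in terms]
    est = fit.theta[idx]
    V = fit.vcov[np.ix_(idx, idx)]
    if not np.isfinite(V).all():
        raise ValueError(f"singular or missing covariance for terms {terms}")
    try:
        chi2 = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance submatrix for terms {terms}") from exc
    df = len(idx)
    return dict(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))
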