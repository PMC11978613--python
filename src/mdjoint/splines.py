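"""Natural cubic spline bases and per-marker design matrices.

The longitudinal mean structure of every marker (square-root dense area,
square-root nondense area, BMI) is a natural cubic spline in age plus
categorical/continuous baseline covariates and a subject-level random
intercept.  The same basis type also parameterizes the log baseline hazard
of the survival submodel.

A natural cubic spline with ``df`` degrees of freedom (excluding the
intercept, which designs carry explicitly) has ``df - 1`` interior knots,
is cubic between knots, has continuous second derivatives, and is linear
beyond the boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "NaturalSplineBasis",
    "MarkerSpec",
    "build_marker_design",
    "marker_mean",
    "CATEGORICAL_LEVELS",
]

# Reference level first; dummies are emitted for the remaining levels in order.
CATEGORICAL_LEVELS = {
    "hrt": ["never", "previous", "current", "missing"],
    "fh": ["no", "yes", "missing"],
    "menopause": ["pre", "peri", "post"],
    "parity": ["0", "1", "2", "3plus", "missing"],
}

# Continuous covariates are centered so intercepts stay interpretable.
BMI_CENTER = 25.0


@dataclass(frozen=True)
class NaturalSplineBasis:
    """Natural cubic spline basis on the age axis.

    Parameters
    ----------
    boundary_knots : (low, high) ages delimiting the cubic region.
    interior_knots : strictly increasing ages inside the boundary.

    The basis has ``df = len(interior_knots) + 1`` columns; together with a
    constant they span the space of natural cubic splines on the given knots.
    Evaluation outside the boundary knots extrapolates linearly (first-order
    Taylor expansion at the boundary, exact because the second derivative
    vanishes there).
    """

    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = ()
    _transform: np.ndarray = field(init=False, repr=False, compare=False)
    _bspline_knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        lo, hi = self.boundary_knots
        interior = np.asarray(self.interior_knots, dtype=float)
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValueError(f"boundary knots must satisfy low < high, got {self.boundary_knots}")
        if interior.size and (interior.min() <= lo or interior.max() >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        if interior.size > 1 and np.any(np.diff(interior) <= 0):
            raise ValueError("interior knots must be strictly increasing")
        knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        nb = len(knots) - 4  # number of cubic B-spline basis functions
        # Natural constraints: second derivative zero at both boundaries.
        d2 = np.vstack(
            [
                _bspline_deriv2(np.array([lo]), knots, nb),
                _bspline_deriv2(np.array([hi]), knots, nb),
            ]
        )
        H = null_space(d2)  # nb x (nb - 2)
        # Remove the constant function (B-spline coefficients all one) from the span.
        c, *_ = np.linalg.lstsq(H, np.ones(nb), rcond=None)
        c = c / np.linalg.norm(c)
        M = null_space(c[None, :])  # (nb-2) x (nb-3)
        object.__setattr__(self, "_bspline_knots", knots)
        object.__setattr__(self, "_transform", H @ M)

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1

    @classmethod
    def from_quantiles(
        cls,
        values,
        df: int = 5,
        boundary_quantiles: tuple[float, float] = (0.01, 0.99),
        clip: tuple[float, float] | None = (40.0, 74.0),
    ) -> "NaturalSplineBasis":
        """Place interior knots at equally spaced quantiles of ``values``.

        Boundary knots sit at the 1st/99th percentiles, optionally clipped to
        the screening age window.
        """
        if df < 1:
            raise ValueError(f"df must be >= 1, got {df}")
        values = np.asarray(values, dtype=float)
        lo, hi = np.quantile(values, boundary_quantiles)
        if clip is not None:
            lo, hi = max(lo, clip[0]), min(hi, clip[1])
        if df == 1:
            return cls((lo, hi))
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(values[(values > lo) & (values < hi)], probs)
        interior = np.unique(interior)
        eps = 1e-6 * (hi - lo)
        interior = interior[(interior > lo + eps) & (interior < hi - eps)]
        return cls((lo, hi), tuple(interior))

    def evaluate(self, ages) -> np.ndarray:
        """Basis matrix, shape ``(len(ages), df)``."""
        x = np.atleast_1d(np.asarray(ages, dtype=float))
        if not np.isfinite(x).all():
            raise ValueError("ages must be finite")
        lo, hi = self.boundary_knots
        xc = np.clip(x, lo, hi)
        B = BSpline.design_matrix(xc, self._bspline_knots, 3).toarray() @ self._transform
        below, above = x < lo, x > hi
        if below.any() or above.any():
            for mask, bk in ((below, lo), (above, hi)):
                if mask.any():
                    b0 = self._eval_point(bk)
                    b1 = self._deriv_point(bk)
                    B[mask] = b0 + np.outer(x[mask] - bk, b1)
        return B

    __call__ = evaluate

    def _eval_point(self, age: float) -> np.ndarray:
        return (
            BSpline.design_matrix(np.array([age]), self._bspline_knots, 3).toarray()
            @ self._transform
        )[0]

    def _deriv_point(self, age: float) -> np.ndarray:
        nb = self._transform.shape[0]
        rows = np.empty(nb)
        for j in range(nb):
            coef = np.zeros(nb)
            coef[j] = 1.0
            rows[j] = BSpline(self._bspline_knots, coef, 3)(age, nu=1)
        return rows @ self._transform

    def to_dict(self) -> dict:
        return {
            "boundary_knots": list(self.boundary_knots),
            "interior_knots": list(self.interior_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalSplineBasis":
        return cls(tuple(d["boundary_knots"]), tuple(d["interior_knots"]))


def _bspline_deriv2(x: np.ndarray, knots: np.ndarray, nb: int) -> np.ndarray:
    """Second derivatives of each cubic B-spline basis function at ``x``."""
    out = np.empty((len(x), nb))
    for j in range(nb):
        coef = np.zeros(nb)
        coef[j] = 1.0
        out[:, j] = BSpline(knots, coef, 3)(x, nu=2)
    return out


@dataclass(frozen=True)
class MarkerSpec:
    """Declarative description of one longitudinal submodel.

    name        : column of the visit table ("nd", "d" or "bmi")
    transform   : scale of the mixed model ("sqrt" for areas, "identity" for BMI)
    spline_df   : degrees of freedom of the age spline
    covariates  : baseline covariates in the fixed effects, from
                  {"bmi_baseline", "hrt", "fh"}
    """

    name: str
    transform: str = "sqrt"
    spline_df: int = 5
    covariates: tuple[str, ...] = ("bmi_baseline", "hrt", "fh")
    random_effects: str = "intercept_only"

    def __post_init__(self):
        if self.name in ("nd", "d") and self.transform != "sqrt":
            raise ValueError(f"marker {self.name!r} must be modeled on the sqrt scale")
        if self.random_effects != "intercept_only":
            raise ValueError("only random intercepts are supported")
        unknown = set(self.covariates) - {"bmi_baseline", "hrt", "fh"}
        if unknown:
            raise ValueError(f"unsupported covariates: {sorted(unknown)}")

    @property
    def visit_column(self) -> str:
        return {"nd": "nd_area", "d": "d_area", "bmi": "bmi"}[self.name]

    def apply_transform(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if self.transform == "sqrt":
            if np.any(raw < 0):
                bad = int(np.flatnonzero(raw < 0)[0])
                raise ValueError(f"negative raw area at row {bad} cannot be sqrt-transformed")
            return np.sqrt(raw)
        return raw

    def n_fixed(self, basis: NaturalSplineBasis) -> int:
        return 1 + basis.df + sum(
            1 if c == "bmi_baseline" else len(CATEGORICAL_LEVELS[c]) - 1 for c in self.covariates
        )

    def fixed_effect_names(self, basis: NaturalSplineBasis) -> list[str]:
        names = [f"{self.name}:intercept"] + [f"{self.name}:age_ns{j + 1}" for j in range(basis.df)]
        for cov in self.covariates:
            if cov == "bmi_baseline":
                names.append(f"{self.name}:bmi_baseline")
            else:
                names += [f"{self.name}:{cov}_{lv}" for lv in CATEGORICAL_LEVELS[cov][1:]]
        return names


def covariate_row(subject, covariates) -> np.ndarray:
    """Dummy-coded baseline covariate vector for one subject.

    ``subject`` is anything with mapping access to ``bmi``, ``hrt``, ``fh``.
    Missing categories are explicit levels, never dropped.
    """
    parts = []
    for cov in covariates:
        if cov == "bmi_baseline":
            parts.append([float(subject["bmi"]) - BMI_CENTER])
        else:
            levels = CATEGORICAL_LEVELS[cov]
            value = str(subject[cov])
            if value not in levels:
                raise ValueError(f"unknown level {value!r} for covariate {cov!r}")
            parts.append([1.0 if value == lv else 0.0 for lv in levels[1:]])
    return np.concatenate(parts) if parts else np.zeros(0)


def covariate_matrix(subjects, covariates) -> tuple[np.ndarray, list[str]]:
    """Vectorized dummy coding for a subject table (one row per subject)."""
    cols, names = [], []
    for cov in covariates:
        if cov == "bmi_baseline":
            cols.append(subjects["bmi"].to_numpy(dtype=float) - BMI_CENTER)
            names.append("bmi_baseline")
        else:
            levels = CATEGORICAL_LEVELS[cov]
            vals = subjects[cov].astype(str).to_numpy()
            bad = set(vals) - set(levels)
            if bad:
                raise ValueError(f"unknown level(s) {sorted(bad)} for covariate {cov!r}")
            for lv in levels[1:]:
                cols.append((vals == lv).astype(float))
                names.append(f"{cov}_{lv}")
    W = np.column_stack(cols) if cols else np.zeros((len(subjects), 0))
    return W, names


def fixed_effects_matrix(ages, subject, spec: MarkerSpec, basis: NaturalSplineBasis) -> np.ndarray:
    """[1 | ns(age) | covariate dummies] for one subject at the given ages."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    n = len(ages)
    w = covariate_row(subject, spec.covariates)
    return np.hstack(
        [np.ones((n, 1)), basis.evaluate(ages), np.broadcast_to(w, (n, len(w)))]
    )


def build_marker_design(visits, subject, spec: MarkerSpec, basis: NaturalSplineBasis):
    """Response vector (transformed scale), fixed-effects matrix and
    random-intercept indicator for one subject's visits.

    ``visits`` is a DataFrame slice with an ``age`` column and the marker's
    raw column; rows where the marker is absent (NaN) are dropped.
    """
    col = spec.visit_column
    obs = visits[np.isfinite(visits[col].to_numpy(dtype=float))]
    y = spec.apply_transform(obs[col].to_numpy(dtype=float))
    X = fixed_effects_matrix(obs["age"].to_numpy(dtype=float), subject, spec, basis)
    Z = np.ones((len(y), 1))
    return y, X, Z


def marker_mean(age, subject, spec: MarkerSpec, basis: NaturalSplineBasis, beta, b_ik=0.0):
    """Model-implied mean trajectory mu_ik(age) = x_ik(age)' beta_k + b_ik."""
    X = fixed_effects_matrix(age, subject, spec, basis)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != len(beta):
        raise ValueError(f"design has {X.shape[1]} columns but beta has {len(beta)}")
    mu = X @ beta + b_ik
    return mu if np.ndim(age) else float(mu[0])
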