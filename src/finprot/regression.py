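"""Weighted probit determinants model with robust SEs and marginal effects.

The model regresses a CHE/MI flag on an urban dummy, income-quartile dummies
(Q1 reference), family size, log per-capita consumption, log per-capita food
spending, and province fixed effects (first province reference), maximizing
the weight-scaled probit log-likelihood sum(w_i * ll_i). Weights are
normalized to mean one before fitting so robust (sandwich) standard errors
stay on the sample-size scale.

Average marginal effects are computed over the estimation sample: the
weighted mean of phi(x'b)*b_j for continuous covariates, and the weighted
mean discrete change Phi(x1'b) - Phi(x0'b) for dummies, with delta-method
standard errors propagated through the robust coefficient covariance.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

MAX_ITERATIONS = 200
GRADIENT_TOL = 1e-6

#: Non-fixed-effect covariates of the standard specification, in report order.
CORE_COVARIATES = (
    "urban",
    "q2",
    "q3",
    "q4",
    "family_size",
    "log_consumption_pc",
    "log_food_pc",
)


class SeparationError(RuntimeError):
    """A covariate perfectly separates the outcome; the MLE does not exist."""


@dataclasses.dataclass
class DesignReport:
    """Row/column accounting from :func:`build_design`."""

    n_input: int = 0
    n_dropped_nonpositive: int = 0
    n_used: int = 0
    non_identified: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ProbitFit:
    """Fitted weighted probit: coefficients, robust covariance, and AMEs."""

    coefficients: Mapping[str, float]
    robust_se: Mapping[str, float]
    cov: np.ndarray
    columns: list[str]
    n_used: int
    converged: bool
    dropped_collinear: list[str] = dataclasses.field(default_factory=list)
    ame: pd.DataFrame | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.columns])


def build_design(
    records: pd.DataFrame,
    outcome: str | None = None,
) -> tuple[pd.DataFrame, pd.Series | None, pd.Series, DesignReport]:
    """Assemble the design matrix for the standard determinants model.

    ``records`` must carry the household fields, an ``income_quartile``
    column, and (unless ``outcome`` is None, e.g. for simulation test beds)
    the outcome flag column. Rows with nonpositive consumption or food
    expenditure (log domain) are dropped and counted. Returns
    (design, outcome, weights, report); the design includes a constant,
    the core covariates, and province dummies (first province as reference).
    """
    report = DesignReport(n_input=len(records))
    ok = (records["consumption_total"] > 0) & (records["food_expenditure"] > 0)
    report.n_dropped_nonpositive = int((~ok).sum())
    df = records.loc[ok].copy()
    report.n_used = len(df)
    if len(df) == 0:
        raise ValueError("no rows left after dropping nonpositive log-domain values")

    y = None
    if outcome is not None:
        y = df[outcome].astype(float)
        if y.nunique() < 2:
            raise ValueError(
                f"outcome {outcome!r} is constant ({y.iloc[0]:.0f}) in the "
                "estimation sample; not estimable"
            )

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["urban"] = df["urban"].astype(float)
    for q in ("Q2", "Q3", "Q4"):
        X[q.lower()] = (df["income_quartile"] == q).astype(float)
    X["family_size"] = df["family_size"].astype(float)
    X["log_consumption_pc"] = np.log(df["consumption_total"] / df["family_size"])
    X["log_food_pc"] = np.log(df["food_expenditure"] / df["family_size"])

    provinces = sorted(df["province"].unique())
    for p in provinces[1:]:  # first province is the reference
        X[f"province_{p}"] = (df["province"] == p).astype(float)

    for col in CORE_COVARIATES:
        if col in X.columns and X[col].nunique() < 2:
            report.non_identified.append(col)
            warnings.warn(
                f"covariate {col!r} is constant in the estimation sample and is "
                "not identified",
                UserWarning,
                stacklevel=2,
            )

    return X, y, df["weight"].astype(float), report


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns beyond the numerical rank, via pivoted QR."""
    A = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(A)
    if r == A.shape[1]:
        return X, []
    _, _, piv = qr(A, mode="economic", pivoting=True)
    keep = sorted(piv[:r])
    kept_cols = [X.columns[i] for i in keep]
    dropped = [c for c in X.columns if c not in kept_cols]
    return X[kept_cols], dropped


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    """Raise if a single covariate perfectly separates the outcome."""
    y = np.asarray(y, dtype=bool)
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy(dtype=float)
        v1, v0 = v[y], v[~y]
        if v1.size == 0 or v0.size == 0:
            continue
        if v1.min() > v0.max() or v1.max() < v0.min():
            raise SeparationError(
                f"covariate {col!r} perfectly separates the outcome; "
                "probit MLE does not exist"
            )


def fit_probit(
    design: pd.DataFrame,
    outcome,
    weights,
    compute_ame: bool = True,
) -> ProbitFit:
    """Maximize the weight-scaled probit likelihood; sandwich covariance.

    Weights are normalized to mean 1 (scale of the robust SEs). Collinear
    columns are dropped with a report; single-covariate perfect separation is
    a :class:`SeparationError`. Convergence follows the IRLS criterion with
    tolerance 1e-6 and at most 200 iterations; a non-converged fit is
    returned with ``converged=False`` rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; not estimable")
    w = w / w.mean()

    X, dropped = _drop_collinear(design)
    _check_separation(X, y)

    model = sm.GLM(
        y,
        X,
        family=sm.families.Binomial(link=sm.families.links.Probit()),
        var_weights=w,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = model.fit(cov_type="HC1", maxiter=MAX_ITERATIONS, tol=GRADIENT_TOL)

    cols = list(X.columns)
    fit = ProbitFit(
        coefficients={c: float(b) for c, b in zip(cols, res.params)},
        robust_se={c: float(s) for c, s in zip(cols, res.bse)},
        cov=np.asarray(res.cov_params()),
        columns=cols,
        n_used=int(len(y)),
        converged=bool(getattr(res, "converged", True)),
        dropped_collinear=dropped,
    )
    if compute_ame and fit.converged:
        fit.ame = marginal_effects(fit, X, w)
    return fit


def _is_dummy(v: np.ndarray) -> bool:
    return np.all(np.isin(v, (0.0, 1.0)))


def marginal_effects(
    fit: ProbitFit,
    design: pd.DataFrame,
    weights=None,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average marginal effects with delta-method robust standard errors.

    Continuous covariate j: AME = weighted mean of phi(x'b) * b_j.
    Dummy covariate j: weighted mean of Phi(x'b | x_j=1) - Phi(x'b | x_j=0).
    Gradients with respect to b are propagated through the robust coefficient
    covariance. Fixed-effect and constant columns are excluded by default.
    """
    X = design[fit.columns].to_numpy(dtype=float)
    b = fit.params
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    if covariates is None:
        covariates = [
            c
            for c in fit.columns
            if c != "const" and not c.startswith("province_")
        ]

    xb = X @ b
    phi = stats.norm.pdf(xb)
    rows = []
    for name in covariates:
        j = fit.columns.index(name)
        col = X[:, j]
        if _is_dummy(col):
            X1, X0 = X.copy(), X.copy()
            X1[:, j], X0[:, j] = 1.0, 0.0
            z1, z0 = X1 @ b, X0 @ b
            ame = float(w @ (stats.norm.cdf(z1) - stats.norm.cdf(z0)))
            grad = (stats.norm.pdf(z1)[:, None] * X1 - stats.norm.pdf(z0)[:, None] * X0)
            g = w @ grad
        else:
            ame = float(w @ phi * b[j])
            # d/db_k of mean(phi(xb) b_j): -xb*phi*x_k*b_j, plus phi at k=j
            g = w @ ((-xb * phi)[:, None] * X * b[j])
            g[j] += float(w @ phi)
        se = float(np.sqrt(g @ fit.cov @ g))
        z = ame / se if se > 0 else np.nan
        rows.append(
            {
                "covariate": name,
                "ame": ame,
                "robust_se": se,
                "z": z,
                "p_value": 2 * stats.norm.sf(abs(z)) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
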