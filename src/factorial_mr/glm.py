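"""Logistic and univariable linear fits: the numeric substrate.

Logistic regression is fitted by iteratively reweighted least squares
(IRLS) with the coefficient covariance taken as the inverse observed
information — for the canonical logit link this coincides with the
expected information, and it is the covariance the delta-method RERI
confidence intervals propagate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ABS_COEF = 15.0  # |logit| beyond this flags separation / divergence


class FitError(RuntimeError):
    """Model fitting failed (separation, rank deficiency, non-convergence)."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class LogisticFit:
    """A fitted logistic regression with coefficient covariance."""

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    n: int
    converged: bool
    loglik: float
    loglik_trace: list[float]

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.names):
            raise ValueError("coefficient / name length mismatch")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance not symmetric")

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"term {name!r} not in fit") from None

    def term(self, name: str) -> tuple[float, float]:
        """(coefficient, SE) for a named term."""
        i = self.index(name)
        return float(self.coef[i]), float(self.se[i])


@dataclass
class LinearFit:
    """Univariable ordinary least squares fit."""

    slope: float
    intercept: float
    r2: float
    f_stat: float
    n: int
    slope_se: float
    slope_ci: tuple[float, float]


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``design`` must include the intercept column. Rows with any
    non-finite entry (in design or outcome) are dropped (complete-case).
    Convergence is declared when the largest coefficient change falls
    below ``tol``; a coefficient drifting beyond 15 on the logit scale
    raises a separation error.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design / outcome shape mismatch")
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length does not match design columns")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if n <= p:
        raise FitError("fewer complete-case rows than model terms")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("design matrix is rank deficient")
    if y.min() == y.max():
        raise FitError("degenerate outcome: all 0 or all 1")

    beta = np.zeros(p)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        trace.append(_loglik(y, eta))
        w = mu * (1.0 - mu)
        # Newton step on the score; solve (X' W X) delta = X'(y - mu)
        XtWX = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"information matrix singular: {exc}", trace)
        beta = beta + delta
        if np.abs(beta).max() > MAX_ABS_COEF:
            raise FitError(
                "perfect separation suspected (coefficient beyond "
                f"{MAX_ABS_COEF} on logit scale)",
                trace,
            )
        if np.abs(delta).max() < tol:
            converged = True
            break
    if not converged:
        raise FitError(f"IRLS did not converge in {max_iter} iterations", trace)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    cov = (cov + cov.T) / 2.0
    return LogisticFit(
        names=list(names),
        coef=beta,
        cov=cov,
        n=n,
        converged=True,
        loglik=_loglik(y, eta),
        loglik_trace=trace,
    )


def fit_linear_univariable(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS of ``y`` on a single predictor ``x`` (complete-case).

    Reports the slope with Wald 95% CI, R-squared, and the F statistic,
    which for a univariable fit equals ``(n - 2) R^2 / (1 - R^2)``.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete cases")
    if x.std() == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    f_stat = (n - 2) * r2 / (1 - r2) if r2 < 1 else np.inf
    half = 1.96 * res.stderr
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        f_stat=float(f_stat),
        n=n,
        slope_se=float(res.stderr),
        slope_ci=(float(res.slope - half), float(res.slope + half)),
    )


def build_design(
    frame, terms: list[str], categorical: tuple[str, ...] = ("batch",)
) -> tuple[np.ndarray, list[str]]:
    """Assemble an intercept-led design matrix from a cohort DataFrame.

    Categorical columns (genotyping batch) are one-hot encoded with the
    first level dropped; everything else enters as-is.
    """
    import pandas as pd

    cols: list[np.ndarray] = [np.ones(len(frame))]
    names: list[str] = ["intercept"]
    for t in terms:
        if t in categorical:
            dummies = pd.get_dummies(frame[t], prefix=t, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(str(c))
        else:
            cols.append(np.asarray(frame[t], dtype=float))
            names.append(t)
    return np.column_stack(cols), names
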