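"""Additive-interaction statistics: RERI, its confidence intervals,
validity checks, the additive term, and fixed-effect meta-analysis.

The relative excess risk due to interaction for two binary (or
unit-contrast continuous) exposures is

    RERI = OR11 - OR10 - OR01 + 1,

where OR11 is the odds ratio of the doubly exposed group against the
doubly unexposed reference and OR10 / OR01 the singly exposed groups.
RERI = 0 means the two exposures' odds-ratio effects are exactly
additive; positive values indicate super-additive (synergistic)
interaction. RERI estimates are only considered valid when all three
component odds ratios exceed 1; otherwise the exposure coding no longer
places the reference at lowest risk and the estimate must be
interpreted with caution.

The default confidence interval is the delta method: the RERI is a
smooth function of the three log-odds coefficients, so its variance is
g' Sigma g with g the gradient and Sigma the coefficient covariance.
A nonparametric percentile bootstrap over individuals is available as
an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import FitError, LogisticFit, fit_logistic

Z95 = 1.96  # 95% Wald intervals throughout, matching report conventions


@dataclass
class OddsRatioEstimate:
    """Odds ratio with Woolf (log-scale Wald) 95% CI."""

    or_value: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.or_value <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")


@dataclass
class RERIResult:
    """RERI point estimate with SE/CI, component ORs, and validity flag."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # "delta" or "bootstrap"
    valid: bool
    or11: float
    or10: float
    or01: float

    def __post_init__(self) -> None:
        implied = self.or11 - self.or10 - self.or01 + 1.0
        if abs(self.estimate - implied) > 1e-10:
            raise ValueError("RERI inconsistent with its component ORs")

    @property
    def caution(self) -> str:
        return "" if self.valid else "interpret with caution: component OR <= 1"


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance pooled estimate."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    weights: np.ndarray  # normalized to sum 1


def odds_ratio_2x2(
    cases_exposed: float,
    noncases_exposed: float,
    cases_ref: float,
    noncases_ref: float,
) -> OddsRatioEstimate:
    """Closed-form 2x2 odds ratio with Woolf standard error.

    OR = (a d)/(c b) with a = exposed cases, b = exposed non-cases,
    c = reference cases, d = reference non-cases;
    SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d). No continuity correction:
    a zero cell is an error.
    """
    a, b, c, d = cases_exposed, noncases_exposed, cases_ref, noncases_ref
    if min(a, b, c, d) <= 0:
        raise ValueError("zero or negative cell in 2x2 table")
    or_value = (a * d) / (c * b)
    log_or = np.log(or_value)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioEstimate(
        or_value=float(or_value),
        log_or=float(log_or),
        se_log_or=float(se),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
    )


def reri_from_ors(or11: float, or10: float, or01: float) -> float:
    """RERI = OR11 - OR10 - OR01 + 1 from three positive odds ratios."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return float(or11 - or10 - or01 + 1.0)


def additive_term(b1: float, b2: float, b3: float) -> float:
    """Joint OR of both exposures, exp(b1 + b2 + b3) — the product of the
    two per-exposure ORs and the cross-product OR."""
    s = b1 + b2 + b3
    if not np.isfinite(s):
        raise ValueError("non-finite coefficient")
    return float(np.exp(s))


def check_validity(or11: float, or10: float, or01: float) -> bool:
    """True iff all component ORs are strictly above 1 (the condition for
    a directly interpretable RERI)."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return bool(or11 > 1 and or10 > 1 and or01 > 1)


def _component_ors(
    coef: np.ndarray, design_2x2: bool, contrast: tuple[float, float]
) -> tuple[float, float, float]:
    """(OR11, OR10, OR01) implied by (b1, b2, b3).

    2x2 design: b1, b2, b3 are the group-1 (second exposure only),
    group-2 (first exposure only) and group-3 (both) indicator
    coefficients, so OR01 = exp(b1), OR10 = exp(b2), OR11 = exp(b3).
    Continuous design: b1, b2 are the two risk-increasing standardized
    scores and b3 their cross-product, evaluated at contrast (c1, c2):
    OR10 = exp(c1 b1), OR01 = exp(c2 b2), OR11 = exp(c1 b1 + c2 b2 + c1 c2 b3).
    """
    b1, b2, b3 = coef
    if design_2x2:
        return float(np.exp(b3)), float(np.exp(b2)), float(np.exp(b1))
    c1, c2 = contrast
    return (
        float(np.exp(c1 * b1 + c2 * b2 + c1 * c2 * b3)),
        float(np.exp(c1 * b1)),
        float(np.exp(c2 * b2)),
    )


def _reri_gradient(
    coef: np.ndarray, design_2x2: bool, contrast: tuple[float, float]
) -> np.ndarray:
    b1, b2, b3 = coef
    if design_2x2:
        return np.array([-np.exp(b1), -np.exp(b2), np.exp(b3)])
    c1, c2 = contrast
    joint = np.exp(c1 * b1 + c2 * b2 + c1 * c2 * b3)
    return np.array(
        [
            c1 * joint - c1 * np.exp(c1 * b1),
            c2 * joint - c2 * np.exp(c2 * b2),
            c1 * c2 * joint,
        ]
    )


def reri_from_coefficients(
    coef: np.ndarray,
    cov: np.ndarray,
    design_2x2: bool = True,
    contrast: tuple[float, float] = (1.0, 1.0),
) -> RERIResult:
    """Delta-method RERI from three coefficients and their 3x3 covariance."""
    coef = np.asarray(coef, dtype=float)
    cov = np.asarray(cov, dtype=float)
    or11, or10, or01 = _component_ors(coef, design_2x2, contrast)
    est = reri_from_ors(or11, or10, or01)
    g = _reri_gradient(coef, design_2x2, contrast)
    if not np.isfinite(g).all():
        raise ValueError("non-finite gradient in delta method")
    var = float(g @ cov @ g)
    se = float(np.sqrt(max(var, 0.0)))
    return RERIResult(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        method="delta",
        valid=check_validity(or11, or10, or01),
        or11=or11,
        or10=or10,
        or01=or01,
    )


def reri_from_fit(
    fit: LogisticFit,
    terms: tuple[str, str, str],
    design_2x2: bool = True,
    contrast: tuple[float, float] = (1.0, 1.0),
    method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
    refit: tuple[np.ndarray, np.ndarray] | None = None,
) -> RERIResult:
    """RERI from a fitted logistic model.

    ``terms`` names the three coefficients: for a 2x2 factorial fit the
    three group indicators (group 1, group 2, group 3); for a continuous
    fit the two risk-increasing score terms and their cross-product.
    ``method='bootstrap'`` requires ``refit=(design, outcome)`` — the
    rows are resampled with replacement and the model refitted; the CI
    is the percentile interval and the SE the bootstrap SD.
    """
    import warnings

    idx = [fit.index(t) for t in terms]
    coef = fit.coef[idx]
    cov = fit.cov[np.ix_(idx, idx)]
    delta = reri_from_coefficients(coef, cov, design_2x2, contrast)
    if method == "delta":
        return delta
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    if refit is None:
        raise ValueError("bootstrap requires refit=(design, outcome)")
    if n_boot < 200:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable", stacklevel=2)
    X, y = refit
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    draws = np.empty(n_boot)
    draws.fill(np.nan)
    for b in range(n_boot):
        rows = rng.integers(0, n, size=n)
        try:
            bfit = fit_logistic(X[rows], y[rows], names=fit.names)
        except FitError:
            continue  # degenerate resample; leave NaN
        bcoef = bfit.coef[idx]
        o11, o10, o01 = _component_ors(bcoef, design_2x2, contrast)
        draws[b] = reri_from_ors(o11, o10, o01)
    ok = draws[np.isfinite(draws)]
    if ok.size < n_boot * 0.5:
        raise RuntimeError("too many degenerate bootstrap resamples")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return RERIResult(
        estimate=delta.estimate,
        se=float(ok.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        method="bootstrap",
        valid=delta.valid,
        or11=delta.or11,
        or10=delta.or10,
        or01=delta.or01,
    )


def meta_fixed(estimates, ses) -> MetaResult:
    """Fixed-effect inverse-variance pooling of study estimates."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates / SEs length mismatch")
    if est.size < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    if (se <= 0).any():
        raise ValueError("SEs must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    return MetaResult(
        estimate=pooled,
        se=pooled_se,
        ci_low=pooled - Z95 * pooled_se,
        ci_high=pooled + Z95 * pooled_se,
        weights=w / w.sum(),
    )
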