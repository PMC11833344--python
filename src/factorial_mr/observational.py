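"""Traditional cross-sectional analyses of measured BMI and 25(OH)D.

Serum 25(OH)D varies strongly with season of blood draw, so measured
values are first recentred to the autumn mean: each value has its own
season's mean subtracted and the autumn mean added back. The continuous
model then regresses psoriasis status on 25(OH)D per 10 nmol/l
*decrease*, BMI per 5 kg/m^2 increase, and their cross-product; the 2x2
model dichotomizes 25(OH)D at 25 nmol/l (deficiency) and BMI at the
WHO public-health action threshold of 27.5 kg/m^2 and compares the four
combined groups against the doubly-unexposed reference, both unadjusted
(closed-form odds ratios) and adjusted for age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import build_design, fit_logistic
from .interaction import (
    RERIResult,
    additive_term,
    odds_ratio_2x2,
    reri_from_fit,
)
from .io_tables import ResultRow

SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
VITD_DEFICIENCY_NMOL_L = 25.0
BMI_ACTION_THRESHOLD = 27.5  # WHO proposed threshold for public health action


@dataclass
class SeasonModel:
    """Per-season means of measured 25(OH)D; reference season is autumn."""

    season_means: dict[str, float]

    @property
    def autumn_mean(self) -> float:
        return self.season_means["autumn"]


def season_adjust(
    vitd: np.ndarray, draw_month: np.ndarray
) -> tuple[np.ndarray, SeasonModel]:
    """Recentre 25(OH)D to the autumn mean.

    adjusted = raw - mean(season of draw) + mean(autumn). Missing values
    stay missing; every season must be observed at least once among the
    non-missing values.
    """
    vitd = np.asarray(vitd, dtype=float)
    month = np.asarray(draw_month, dtype=float)
    present = np.isfinite(vitd)
    if not np.isfinite(month[present]).all():
        raise ValueError("draw month missing for a sample with measured 25(OH)D")
    seasons = np.array(
        [SEASON_OF_MONTH[int(m)] if np.isfinite(m) else "" for m in month]
    )
    means: dict[str, float] = {}
    for s in ("winter", "spring", "summer", "autumn"):
        mask = present & (seasons == s)
        if not mask.any():
            raise ValueError(f"no 25(OH)D observations in season {s!r}")
        means[s] = float(vitd[mask].mean())
    model = SeasonModel(season_means=means)
    adjusted = vitd.copy()
    for s, m in means.items():
        mask = present & (seasons == s)
        adjusted[mask] = vitd[mask] - m + model.autumn_mean
    return adjusted, model


def dichotomize_exposures(cohort: pd.DataFrame) -> pd.DataFrame:
    """Binary exposure indicators from season-adjusted 25(OH)D and BMI.

    Requires a ``vitd_adj`` column (see :func:`season_adjust`). Low
    25(OH)D is strictly below 25 nmol/l; high BMI is strictly above
    27.5 kg/m^2. Returns the cohort with ``low_vitd``, ``high_bmi`` and
    the combined ``obs_group`` (0 = neither, 1 = low vitD only,
    2 = high BMI only, 3 = both), NaN where either measure is missing.
    """
    out = cohort.copy()
    out["low_vitd"] = np.where(
        out["vitd_adj"].notna(), (out["vitd_adj"] < VITD_DEFICIENCY_NMOL_L), np.nan
    )
    out["high_bmi"] = np.where(
        out["bmi"].notna(), (out["bmi"] > BMI_ACTION_THRESHOLD), np.nan
    )
    complete = out["low_vitd"].notna() & out["high_bmi"].notna()
    grp = np.full(len(out), np.nan)
    lv = out["low_vitd"].to_numpy(float)
    hb = out["high_bmi"].to_numpy(float)
    grp[complete.to_numpy()] = (lv + 2 * hb)[complete.to_numpy()]
    out["obs_group"] = grp
    return out


@dataclass
class ObservationalReport:
    """Rows of an observational analysis plus its RERI."""

    rows: list[ResultRow]
    reri: RERIResult
    reri_unadjusted: RERIResult | None = None
    n: int = 0


def run_observational_continuous(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = ("age", "sex")
) -> ObservationalReport:
    """Continuous observational interaction model.

    Predictors: season-adjusted 25(OH)D per 10 nmol/l decrease
    (``-vitd_adj / 10``), BMI per 5 kg/m^2 increase (``bmi / 5``), and
    their cross-product, plus covariates. The decrease coding is a
    sign-flip of the predictor, so both exposure terms point in the
    risk-increasing direction and RERI is evaluated at the (+1, +1)
    contrast.
    """
    df = cohort.copy()
    df["vitd_dec10"] = -df["vitd_adj"] / 10.0
    df["bmi_inc5"] = df["bmi"] / 5.0
    df["cross"] = df["vitd_dec10"] * df["bmi_inc5"]
    terms = ["vitd_dec10", "bmi_inc5", "cross", *covariates]
    X, names = build_design(df, terms)
    y = df["psoriasis"].to_numpy(float)
    fit = fit_logistic(X, y, names=names)
    reri = reri_from_fit(
        fit, ("vitd_dec10", "bmi_inc5", "cross"), design_2x2=False
    )
    rows = []
    for term, label in [
        ("vitd_dec10", "25(OH)D per 10 nmol/l decrease"),
        ("bmi_inc5", "BMI per 5 kg/m^2 increase"),
        ("cross", "BMI x 25(OH)D cross-product"),
    ]:
        b, se = fit.term(term)
        rows.append(
            ResultRow(
                analysis="observational_continuous",
                term=label,
                estimate=float(np.exp(b)),
                se=se,
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
            )
        )
    b1 = fit.term("vitd_dec10")[0]
    b2 = fit.term("bmi_inc5")[0]
    b3 = fit.term("cross")[0]
    rows.append(
        ResultRow(
            analysis="observational_continuous",
            term="additive term exp(b1+b2+b3)",
            estimate=additive_term(b1, b2, b3),
        )
    )
    rows.append(_reri_row("observational_continuous", reri))
    return ObservationalReport(rows=rows, reri=reri, n=fit.n)


def _reri_row(analysis: str, reri: RERIResult) -> ResultRow:
    return ResultRow(
        analysis=analysis,
        term=f"RERI ({reri.method})",
        estimate=reri.estimate,
        se=reri.se,
        ci_low=reri.ci_low,
        ci_high=reri.ci_high,
        valid=reri.valid,
        extra={"caution": reri.caution},
    )


def _counts(df: pd.DataFrame, mask_exposed, mask_ref) -> tuple[int, int, int, int]:
    y = df["psoriasis"]
    a = int(((y == 1) & mask_exposed).sum())
    b = int(((y == 0) & mask_exposed).sum())
    c = int(((y == 1) & mask_ref).sum())
    d = int(((y == 0) & mask_ref).sum())
    return a, b, c, d


def run_observational_2x2(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = ("age", "sex")
) -> ObservationalReport:
    """2x2 observational analysis on dichotomized exposures.

    Emits the two single-exposure marginal odds ratios, the four
    combined-group comparisons (unadjusted closed-form and
    covariate-adjusted logistic), and the RERI for both columns.
    Complete-case on both exposures for the combined block; each single
    block is complete-case on its own exposure.
    """
    df = dichotomize_exposures(cohort) if "obs_group" not in cohort else cohort.copy()
    rows: list[ResultRow] = []
    # single associations, each on its own complete-case subset
    for flag, label in [("low_vitd", "25(OH)D < 25"), ("high_bmi", "BMI > 27.5")]:
        sub = df[df[flag].notna()]
        est = odds_ratio_2x2(*_counts(sub, sub[flag] == 1, sub[flag] == 0))
        rows.append(
            ResultRow(
                analysis="observational_2x2_single",
                term=f"{label} (unadjusted)",
                estimate=est.or_value,
                se=est.se_log_or,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
            )
        )
    sub = df[df["obs_group"].notna()].copy()
    if sub.empty:
        raise ValueError("no complete cases on both exposures")
    group = sub["obs_group"].astype(int)
    ors = {}
    for g, label in [(1, "low vitD only"), (2, "high BMI only"), (3, "both exposed")]:
        a, b, c, d = _counts(sub, group == g, group == 0)
        if min(a, b, c, d) == 0:
            raise ValueError(f"empty cell in combined 2x2 block (group {g})")
        est = odds_ratio_2x2(a, b, c, d)
        ors[g] = est
        rows.append(
            ResultRow(
                analysis="observational_2x2_combined",
                term=f"{label} (unadjusted)",
                estimate=est.or_value,
                se=est.se_log_or,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                extra={"cases": a, "noncases": b},
            )
        )
    # group log-ORs vs a shared reference are correlated through the
    # reference cells; the saturated fit reproduces the closed-form ORs
    # exactly and supplies the joint covariance for the delta-method CI
    Xs, names = build_design(
        sub.assign(
            g1=(group == 1).astype(float),
            g2=(group == 2).astype(float),
            g3=(group == 3).astype(float),
        ),
        ["g1", "g2", "g3"],
    )
    sat = fit_logistic(Xs, sub["psoriasis"].to_numpy(float), names=names)
    reri_unadj = reri_from_fit(sat, ("g1", "g2", "g3"), design_2x2=True)
    rows.append(_reri_row("observational_2x2_unadjusted", reri_unadj))
    # adjusted column
    Xa, names_a = build_design(
        sub.assign(
            g1=(group == 1).astype(float),
            g2=(group == 2).astype(float),
            g3=(group == 3).astype(float),
        ),
        ["g1", "g2", "g3", *covariates],
    )
    adj = fit_logistic(Xa, sub["psoriasis"].to_numpy(float), names=names_a)
    for term, label in [("g1", "low vitD only"), ("g2", "high BMI only"), ("g3", "both exposed")]:
        b, se = adj.term(term)
        rows.append(
            ResultRow(
                analysis="observational_2x2_combined",
                term=f"{label} (adjusted)",
                estimate=float(np.exp(b)),
                se=se,
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
            )
        )
    reri_adj = reri_from_fit(adj, ("g1", "g2", "g3"), design_2x2=True)
    rows.append(_reri_row("observational_2x2_adjusted", reri_adj))
    return ObservationalReport(
        rows=rows, reri=reri_adj, reri_unadjusted=reri_unadj, n=len(sub)
    )
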