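"""Factorial MR orchestration: 2x2 and continuous designs, Wald-ratio
scaling to phenotype units, and instrument diagnostics.

The 2x2 design dichotomizes both polygenic scores at their medians and
contrasts the four groups; the continuous design enters both
standardized scores (the 25(OH)D score flipped to its risk-increasing
orientation) plus their cross-product. Both report odds ratios, the
additive term, and the RERI with a delta-method CI by default. Scaling
rescales log-odds coefficients by target / first-stage effect (5 kg/m^2
of BMI, 10 nmol/l of 25(OH)D) with the covariance transformed
conformably, and the RERI is recomputed from the scaled coefficients —
RERI is non-linear in the coefficients, so it cannot simply be
multiplied through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import LinearFit, LogisticFit, build_design, fit_logistic, fit_linear_univariable
from .interaction import RERIResult, additive_term, reri_from_coefficients, reri_from_fit
from .io_tables import ResultRow
from .prs import FactorialAssignment, PRSVector, assign_factorial_groups

MR_COVARIATES: tuple[str, ...] = ("age", "sex", "batch") + tuple(
    f"pc{i}" for i in range(1, 21)
)


@dataclass
class FactorialMRReport:
    """Result of one factorial MR analysis (2x2 or continuous)."""

    design: str  # "2x2" or "continuous"
    rows: list[ResultRow]
    reri: RERIResult
    fit: LogisticFit
    terms: tuple[str, str, str]
    covariates: tuple[str, ...]
    prs_versions: str = ""
    contrast: tuple[float, float] = (1.0, 1.0)


@dataclass
class InstrumentDiagnostics:
    """Instrument strength and score-confounder association table."""

    trait: str
    first_stage: LinearFit
    confounder_fits: dict[str, LinearFit] = field(default_factory=dict)

    def rows(self) -> list[ResultRow]:
        fs = self.first_stage
        out = [
            ResultRow(
                analysis=f"first_stage_{self.trait}",
                term="beta per 1 SD of score",
                estimate=fs.slope,
                se=fs.slope_se,
                ci_low=fs.slope_ci[0],
                ci_high=fs.slope_ci[1],
                extra={"r2": fs.r2, "f_stat": fs.f_stat, "n": fs.n},
            )
        ]
        for name, f in self.confounder_fits.items():
            out.append(
                ResultRow(
                    analysis=f"confounders_{self.trait}",
                    term=name,
                    estimate=f.slope,
                    se=f.slope_se,
                    ci_low=f.slope_ci[0],
                    ci_high=f.slope_ci[1],
                )
            )
        return out


def _or_row(analysis: str, label: str, b: float, se: float) -> ResultRow:
    return ResultRow(
        analysis=analysis,
        term=label,
        estimate=float(np.exp(b)),
        se=se,
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
    )


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


def run_2x2_factorial(
    cohort: pd.DataFrame,
    bmi_prs: PRSVector,
    vitd_prs: PRSVector,
    covariates: tuple[str, ...] = MR_COVARIATES,
    reri_method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> FactorialMRReport:
    """2x2 factorial MR: psoriasis on the three factorial-group
    indicators (reference = group 0) plus covariates.

    Both scores must be in trait-increasing orientation; the grouping
    dichotomizes each at its median ("equal to or below" = low).
    """
    groups = assign_factorial_groups(bmi_prs, vitd_prs)
    if (groups.counts() == 0).any():
        raise ValueError("empty factorial group")
    df = cohort.copy()
    if list(df["sample_id"]) != groups.sample_ids:
        raise ValueError("cohort and PRS sample ids do not match")
    for g in (1, 2, 3):
        df[f"group{g}"] = (groups.group == g).astype(float)
    X, names = build_design(df, [f"group{g}" for g in (1, 2, 3)] + list(covariates))
    y = df["psoriasis"].to_numpy(float)
    fit = fit_logistic(X, y, names=names)
    terms = ("group1", "group2", "group3")
    reri = reri_from_fit(
        fit, terms, design_2x2=True, method=reri_method, n_boot=n_boot,
        seed=seed, refit=(X, y),
    )
    rows = [
        ResultRow(analysis="mr_2x2", term="factorial group 0", estimate=1.0,
                  extra={"note": "reference"})
    ]
    for g, label in [(1, "factorial group 1"), (2, "factorial group 2"),
                     (3, "factorial group 3")]:
        b, se = fit.term(f"group{g}")
        rows.append(_or_row("mr_2x2", label, b, se))
    rows.append(_reri_row("mr_2x2", reri))
    return FactorialMRReport(
        design="2x2", rows=rows, reri=reri, fit=fit, terms=terms,
        covariates=tuple(covariates),
        prs_versions=f"{bmi_prs.n_variants_used}/{vitd_prs.n_variants_used}",
    )


def run_continuous_factorial(
    cohort: pd.DataFrame,
    bmi_prs: PRSVector,
    vitd_prs_flipped: PRSVector,
    covariates: tuple[str, ...] = MR_COVARIATES,
    contrast: tuple[float, float] = (1.0, 1.0),
    reri_method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> FactorialMRReport:
    """Continuous factorial MR with the cross-product term.

    The 25(OH)D score must be supplied flipped (orientation -1) so a
    +1 unit is 1 SD of genetically *lower* 25(OH)D; the cross-product is
    formed after flipping, and RERI is evaluated at the (+1, +1)
    risk-increasing contrast by default.
    """
    if vitd_prs_flipped.orientation != -1:
        raise ValueError("continuous design expects the flipped 25(OH)D score")
    if bmi_prs.sample_ids != vitd_prs_flipped.sample_ids:
        raise ValueError("sample ids of the two scores do not match")
    df = cohort.copy()
    if list(df["sample_id"]) != bmi_prs.sample_ids:
        raise ValueError("cohort and PRS sample ids do not match")
    z1 = bmi_prs.standardized
    z2 = vitd_prs_flipped.standardized
    if z1 is None or z2 is None:
        raise ValueError("scores must be standardized")
    df["bmi_score"] = z1
    df["vitd_score_dec"] = z2
    df["cross"] = z1 * z2
    X, names = build_design(df, ["bmi_score", "vitd_score_dec", "cross"] + list(covariates))
    y = df["psoriasis"].to_numpy(float)
    fit = fit_logistic(X, y, names=names)
    terms = ("bmi_score", "vitd_score_dec", "cross")
    reri = reri_from_fit(
        fit, terms, design_2x2=False, contrast=contrast, method=reri_method,
        n_boot=n_boot, seed=seed, refit=(X, y),
    )
    rows = []
    for term, label in [
        ("bmi_score", "BMI-PRS (per 1 SD increase)"),
        ("vitd_score_dec", "vitD-PRS (per 1 SD decrease)"),
        ("cross", "cross-product"),
    ]:
        b, se = fit.term(term)
        rows.append(_or_row("mr_continuous", label, b, se))
    b1, b2, b3 = (fit.term(t)[0] for t in terms)
    rows.append(
        ResultRow(analysis="mr_continuous", term="additive term exp(b1+b2+b3)",
                  estimate=additive_term(b1, b2, b3))
    )
    rows.append(_reri_row("mr_continuous", reri))
    return FactorialMRReport(
        design="continuous", rows=rows, reri=reri, fit=fit, terms=terms,
        covariates=tuple(covariates), contrast=contrast,
        prs_versions=f"{bmi_prs.n_variants_used}/{vitd_prs_flipped.n_variants_used}",
    )


def scale_estimates(
    report: FactorialMRReport,
    first_stage_bmi: float,
    first_stage_vitd: float,
    target_bmi: float = 5.0,
    target_vitd: float = 10.0,
) -> FactorialMRReport:
    """Rescale a continuous factorial MR report to phenotype units.

    Wald-ratio rescaling: each exposure log-OR is multiplied by
    target / first-stage effect (kg/m^2 or nmol/l per 1 SD of score),
    the cross-product log-OR by both factors, and the coefficient
    covariance by the same diagonal transform; the RERI is then
    recomputed from the scaled coefficients.
    """
    if first_stage_bmi <= 0 or first_stage_vitd <= 0:
        raise ValueError("first-stage effects must be positive")
    if report.design != "continuous":
        raise ValueError("scaling applies to the continuous design")
    f1 = target_bmi / first_stage_bmi
    f2 = target_vitd / first_stage_vitd
    D = np.diag([f1, f2, f1 * f2])
    idx = [report.fit.index(t) for t in report.terms]
    coef = report.fit.coef[idx] @ D
    cov = D @ report.fit.cov[np.ix_(idx, idx)] @ D
    reri = reri_from_coefficients(coef, cov, design_2x2=False,
                                  contrast=report.contrast)
    labels = [
        f"BMI-PRS (per {target_bmi:g} kg/m^2 increase)",
        f"vitD-PRS (per {target_vitd:g} nmol/l decrease)",
        "cross-product (scaled)",
    ]
    rows = [
        _or_row("mr_continuous_scaled", lab, coef[k], float(np.sqrt(cov[k, k])))
        for k, lab in enumerate(labels)
    ]
    rows.append(
        ResultRow(analysis="mr_continuous_scaled", term="additive term exp(b1+b2+b3)",
                  estimate=additive_term(*coef))
    )
    rows.append(_reri_row("mr_continuous_scaled", reri))
    scaled_fit = LogisticFit(
        names=list(report.terms),
        coef=coef,
        cov=cov,
        n=report.fit.n,
        converged=True,
        loglik=np.nan,
        loglik_trace=[],
    )
    return FactorialMRReport(
        design="continuous", rows=rows, reri=reri, fit=scaled_fit,
        terms=report.terms, covariates=report.covariates,
        contrast=report.contrast, prs_versions=report.prs_versions,
    )


def run_diagnostics(
    cohort: pd.DataFrame,
    prs: PRSVector,
    measured_trait: str,
    candidate_confounders: tuple[str, ...] = ("age", "sex"),
) -> InstrumentDiagnostics:
    """Instrument strength and score-confounder associations.

    First stage: univariable OLS of the measured trait on the
    standardized score (beta per 1 SD, R^2, F). Then each candidate
    confounder is regressed on the score, giving the association table
    used to probe the independence assumption.
    """
    if prs.standardized is None:
        raise ValueError("score must be standardized")
    if list(cohort["sample_id"]) != prs.sample_ids:
        raise ValueError("cohort and PRS sample ids do not match")
    z = prs.standardized
    first = fit_linear_univariable(z, cohort[measured_trait].to_numpy(float))
    conf = {
        name: fit_linear_univariable(z, cohort[name].to_numpy(float))
        for name in candidate_confounders
    }
    return InstrumentDiagnostics(trait=prs.trait, first_stage=first,
                                 confounder_fits=conf)
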