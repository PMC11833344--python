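"""Calibrated synthetic biobank cohorts for the factorial MR pipeline.

The generator emulates the statistical skeleton a large population
biobank presents to these analyses: independent biallelic variants with
published-style weights, polygenic scores explaining a configured share
of trait variance (defaults: R^2 = 4.8% of BMI, 4.6% of 25(OH)D, giving
first-stage effects of ~1.05 kg/m^2 and ~4.23 nmol/l per 1 SD of
score), traits with realistic means/SDs (BMI 27.4/4.8 kg/m^2,
season-adjusted 25(OH)D 54.8/19.7 nmol/l), seasonal offsets on the raw
25(OH)D measurement, and a binary psoriasis outcome with configurable
group-wise odds structure (baseline prevalence 3.1% UKB-like or 9.0%
HUNT-like).

Outcome generation is *group-odds based*, not logistic-with-product:
a logistic model without a product term is a multiplicative null, which
has RERI = (OR10-1)(OR01-1) != 0. The additive-null mode instead sets
the doubly-exposed odds factor to OR10 + OR01 - 1, making the true RERI
exactly zero — the construction the coverage tests require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_tables import GenotypeMatrix, WeightTable, PC_COLUMNS
from .observational import SEASON_OF_MONTH

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort; defaults are UKB-like."""

    n: int = 50_000
    n_variants_bmi: int = 941
    n_variants_vitd: int = 21
    maf_range: tuple[float, float] = (0.05, 0.5)
    r2_bmi: float = 0.048
    r2_vitd: float = 0.046
    bmi_mean: float = 27.4
    bmi_sd: float = 4.8
    vitd_mean: float = 54.8  # season-adjusted scale
    vitd_sd: float = 19.7
    season_offsets: dict = field(
        default_factory=lambda: {
            "winter": -6.0, "spring": -2.0, "summer": 7.0, "autumn": 0.0
        }
    )
    prevalence: float = 0.031
    outcome_mode: str = "additive_null"  # | "specified_reri" | "multiplicative"
    outcome_design: str = "groups"  # | "continuous"
    or_bmi: float = 1.08   # OR10: BMI-exposed-only odds factor
    or_vitd: float = 1.05  # OR01: low-vitD-only odds factor
    reri_true: float = 0.0
    age_mean: float = 56.9
    age_sd: float = 7.9
    female_frac: float = 0.538
    n_batches: int = 3
    miss_bmi: float = 0.003
    miss_vitd: float = 0.088
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        for r2 in (self.r2_bmi, self.r2_vitd):
            if not 0 <= r2 < 1:
                raise ValueError("R^2 must be in [0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        if self.outcome_mode not in {"additive_null", "specified_reri",
                                     "multiplicative"}:
            raise ValueError(f"unknown outcome mode {self.outcome_mode!r}")
        if self.outcome_design not in {"groups", "continuous"}:
            raise ValueError(f"unknown outcome design {self.outcome_design!r}")


@dataclass
class SimTruth:
    """The generating values a recovery test should find."""

    slope_bmi: float       # kg/m^2 per 1 SD of BMI score
    slope_vitd: float      # nmol/l per 1 SD of vitD score
    or01: float            # low-vitD-only odds factor
    or10: float            # BMI-only odds factor
    or11: float            # doubly-exposed odds factor
    reri: float
    baseline_odds: float
    prevalence: float
    seed: int


def calibrate_first_stage(target_r2: float, trait_sd: float) -> float:
    """Slope of trait per 1 SD of a unit-variance score explaining
    ``target_r2`` of the trait variance: sqrt(R^2) * SD(trait)."""
    if not 0 <= target_r2 < 1:
        raise ValueError("target R^2 must be in [0,1)")
    if trait_sd <= 0:
        raise ValueError("trait SD must be positive")
    return float(np.sqrt(target_r2) * trait_sd)


def group_odds_factors(config: SimConfig) -> tuple[float, float, float, float]:
    """Odds multipliers of the four factorial groups under the configured
    outcome mode: (reference, vitD-only, BMI-only, both)."""
    f01, f10 = config.or_vitd, config.or_bmi
    if config.outcome_mode == "additive_null":
        f11 = f10 + f01 - 1.0
    elif config.outcome_mode == "specified_reri":
        f11 = f10 + f01 - 1.0 + config.reri_true
    else:  # multiplicative
        f11 = f10 * f01
    if min(f01, f10, f11) <= 0:
        raise ValueError("configured odds factors imply non-positive odds")
    return 1.0, f01, f10, f11


def true_reri(config: SimConfig) -> float:
    if config.outcome_mode == "additive_null":
        return 0.0  # exact by construction, not a floating residue
    _, f01, f10, f11 = group_odds_factors(config)
    return f11 - f10 - f01 + 1.0


def _solve_baseline_odds(factors: np.ndarray, prevalence: float) -> float:
    """Baseline odds such that the cohort-mean event probability equals
    the configured prevalence."""

    def mean_prev(log_o0: float) -> float:
        o = np.exp(log_o0) * factors
        return float(np.mean(o / (1.0 + o))) - prevalence

    return float(np.exp(brentq(mean_prev, -12.0, 4.0)))


def generate_outcome(
    config: SimConfig,
    rng: np.random.Generator,
    groups: np.ndarray | None = None,
    exposures: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Draw the binary outcome for factorial groups or continuous
    risk-increasing exposures.

    ``groups`` is the 0-3 factorial assignment; ``exposures`` is
    ``(x1, x2)`` with x1 = standardized BMI score and x2 = standardized
    *flipped* (risk-increasing) 25(OH)D score. In the continuous case
    the per-SD analogue of each mode is applied on the odds scale:
    multiplicative -> OR10^x1 * OR01^x2; additive null ->
    OR10^x1 + OR01^x2 - 1; specified RERI adds
    reri_true * max(x1,0) * max(x2,0), so the (+1,+1) contrast carries
    the configured RERI exactly.
    """
    _, f01, f10, f11 = group_odds_factors(config)
    if (groups is None) == (exposures is None):
        raise ValueError("supply exactly one of groups / exposures")
    if groups is not None:
        factors = np.array([1.0, f01, f10, f11])[np.asarray(groups, dtype=int)]
    else:
        x1, x2 = (np.asarray(x, dtype=float) for x in exposures)
        if config.outcome_mode == "multiplicative":
            factors = f10**x1 * f01**x2
        else:
            factors = f10**x1 + f01**x2 - 1.0
            if config.outcome_mode == "specified_reri":
                factors = factors + config.reri_true * np.maximum(x1, 0) * np.maximum(x2, 0)
        if (factors <= 0).any():
            raise ValueError("continuous odds factors non-positive at the tails")
    o0 = _solve_baseline_odds(factors, config.prevalence)
    odds = o0 * factors
    p = odds / (1.0 + odds)
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("implied probability outside (0,1)")
    y = rng.binomial(1, p).astype(int)
    truth = SimTruth(
        slope_bmi=calibrate_first_stage(config.r2_bmi, config.bmi_sd),
        slope_vitd=calibrate_first_stage(config.r2_vitd, config.vitd_sd),
        or01=f01, or10=f10, or11=f11,
        reri=true_reri(config),
        baseline_odds=o0,
        prevalence=config.prevalence,
        seed=config.seed,
    )
    return y, truth


def _draw_score_block(
    rng: np.random.Generator, n: int, m: int, maf_range: tuple[float, float],
    trait: str, id_offset: int,
) -> tuple[np.ndarray, WeightTable, list[str], list[str], list[str], np.ndarray]:
    mafs = rng.uniform(*maf_range, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    weights = rng.normal(0.0, 1.0, size=m)
    pairs = [_ALLELE_PAIRS[int(k)] for k in rng.integers(0, len(_ALLELE_PAIRS), m)]
    ids = [f"rs{id_offset + j}" for j in range(m)]
    wt = WeightTable(
        trait=trait,
        entries=pd.DataFrame(
            {
                "variant_id": ids,
                "effect_allele": [p[0] for p in pairs],
                "other_allele": [p[1] for p in pairs],
                "weight": weights,
            }
        ),
    )
    return dosages, wt, ids, [p[0] for p in pairs], [p[1] for p in pairs], weights


def generate_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, tuple[WeightTable, WeightTable], SimTruth]:
    """Generate one synthetic cohort from a single seed.

    Returns the genotype matrix (both score blocks side by side), the
    cohort phenotype table, the two weight tables (BMI, 25(OH)D) and the
    generating truth. Traits are built as
    mean + slope * standardized_score + Gaussian noise with the noise
    variance chosen so the total SD matches the configured SD; the raw
    stored 25(OH)D additionally carries the season offset of the
    simulated draw month.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    slope_bmi = calibrate_first_stage(config.r2_bmi, config.bmi_sd)
    slope_vitd = calibrate_first_stage(config.r2_vitd, config.vitd_sd)
    for sd, slope in ((config.bmi_sd, slope_bmi), (config.vitd_sd, slope_vitd)):
        if sd**2 - slope**2 < 0:
            raise ValueError("genetic variance exceeds total trait variance")

    gb, wt_bmi, ids_b, ca_b, oa_b, _ = _draw_score_block(
        rng, n, config.n_variants_bmi, config.maf_range, "BMI", 1
    )
    gv, wt_vitd, ids_v, ca_v, oa_v, _ = _draw_score_block(
        rng, n, config.n_variants_vitd, config.maf_range, "25OHD",
        1 + config.n_variants_bmi,
    )
    sample_ids = [f"S{i:07d}" for i in range(n)]
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=ids_b + ids_v,
        counted_alleles=ca_b + ca_v,
        other_alleles=oa_b + oa_v,
        dosages=np.hstack([gb, gv]),
    )

    def _standardize(raw: np.ndarray) -> np.ndarray:
        return (raw - raw.mean()) / raw.std()

    z_bmi = _standardize(gb @ wt_bmi.entries["weight"].to_numpy())
    z_vitd = _standardize(gv @ wt_vitd.entries["weight"].to_numpy())

    bmi = (
        config.bmi_mean + slope_bmi * z_bmi
        + rng.normal(0.0, np.sqrt(config.bmi_sd**2 - slope_bmi**2), n)
    )
    vitd_adj = (
        config.vitd_mean + slope_vitd * z_vitd
        + rng.normal(0.0, np.sqrt(config.vitd_sd**2 - slope_vitd**2), n)
    )
    draw_month = rng.integers(1, 13, size=n)
    offsets = np.array(
        [config.season_offsets[SEASON_OF_MONTH[int(m)]] for m in draw_month]
    )
    # serum concentration cannot go negative; clip the measured value
    vitd_raw = np.clip(vitd_adj + offsets, 0.1, None)

    # factorial exposure status from the generating scores
    bmi_high = z_bmi > np.median(z_bmi)
    vitd_low = z_vitd <= np.median(z_vitd)
    groups = np.select(
        [~bmi_high & ~vitd_low, ~bmi_high & vitd_low, bmi_high & ~vitd_low],
        [0, 1, 2], default=3,
    )
    if config.outcome_design == "groups":
        y, truth = generate_outcome(config, rng, groups=groups)
    else:
        y, truth = generate_outcome(config, rng, exposures=(z_bmi, -z_vitd))

    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": rng.normal(config.age_mean, config.age_sd, n).clip(18, None),
            "sex": rng.binomial(1, config.female_frac, n),
            "batch": [f"b{int(k)}" for k in rng.integers(0, config.n_batches, n)],
        }
    )
    for j, col in enumerate(PC_COLUMNS):
        cohort[col] = rng.normal(0.0, 1.0, n)
    cohort["bmi"] = np.where(rng.random(n) < config.miss_bmi, np.nan, bmi)
    cohort["vitd"] = np.where(rng.random(n) < config.miss_vitd, np.nan, vitd_raw)
    cohort["draw_month"] = draw_month
    cohort["psoriasis"] = y
    return gm, cohort, (wt_bmi, wt_vitd), truth


def hunt_like(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A HUNT-flavoured configuration: higher prevalence, smaller BMI
    instrument R^2, HUNT trait moments."""
    base = config or SimConfig()
    defaults = dict(
        prevalence=0.090, r2_bmi=0.034, bmi_mean=26.4, bmi_sd=4.4,
        age_mean=46.1, age_sd=16.9, female_frac=0.530,
    )
    defaults.update(overrides)
    return replace(base, **defaults)
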