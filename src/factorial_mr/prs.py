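"""Polygenic risk score construction and the 2x2 factorial grouping.

A PRS is the per-individual sum of trait-increasing allele dosages
weighted by published GWAS effect sizes. Scores are standardized to
mean 0, SD 1 over the analysis sample; the 25(OH)D score can be flipped
(negated) so that +1 unit reads "1 SD *decrease* in genetically
predicted 25(OH)D", the risk-increasing orientation used in the
continuous factorial models. Median dichotomization of the two
(unflipped) scores defines the four factorial groups, with the
doubly-low-risk group (BMI score low, vitD score high) as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import GenotypeMatrix, WeightTable


@dataclass
class PRSVector:
    """A polygenic score over one analysis sample.

    ``orientation`` is +1 when a higher score predicts a higher trait
    value (trait-increasing) and -1 after flipping to the
    risk-increasing direction.
    """

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray | None
    trait: str
    n_variants_requested: int
    n_variants_used: int
    orientation: int = +1
    variants_used: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.n_variants_used > self.n_variants_requested:
            raise ValueError("n_variants_used exceeds n_variants_requested")
        if self.standardized is not None:
            z = np.asarray(self.standardized, dtype=float)
            if abs(z.mean()) > 1e-8 or abs(z.std() - 1) > 1e-8:
                raise ValueError("standardized score is not mean 0 / SD 1")
            self.standardized = z


@dataclass
class FactorialAssignment:
    """Factorial group per sample: 0 = BMI-PRS low & vitD-PRS high
    (reference), 1 = both low, 2 = both high, 3 = BMI high & vitD low."""

    sample_ids: list[str]
    group: np.ndarray  # int in {0,1,2,3}

    def counts(self) -> np.ndarray:
        return np.bincount(self.group, minlength=4)


def compute_prs(genotypes: GenotypeMatrix, weights: WeightTable) -> PRSVector:
    """Weighted allele sum of the effect alleles listed in ``weights``.

    Dosages count the genotype file's *counted* allele; when that equals
    the weight table's other allele the dosage is flipped to ``2 - d``.
    Variants absent from the genotypes, or with an allele pair matching
    neither listed allele, are skipped (with a warning for mismatches)
    and reflected in ``n_variants_used``. Missing individual dosages are
    mean-imputed per variant from the non-missing samples.
    """
    gidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    raw = np.zeros(genotypes.n_samples)
    used: list[str] = []
    for row in weights.entries.itertuples(index=False):
        j = gidx.get(row.variant_id)
        if j is None:
            continue
        counted = genotypes.counted_alleles[j]
        other = genotypes.other_alleles[j]
        d = genotypes.dosages[:, j].copy()
        miss = ~np.isfinite(d)
        if miss.any():
            if miss.all():
                continue  # no information at all for this variant
            d[miss] = d[~miss].mean()  # 2 x allele frequency of non-missing
        if counted == row.effect_allele and other == row.other_allele:
            pass
        elif counted == row.other_allele and other == row.effect_allele:
            d = 2.0 - d
        else:
            warnings.warn(
                f"allele mismatch for {row.variant_id} "
                f"({counted}/{other} vs {row.effect_allele}/{row.other_allele}); "
                "variant skipped",
                stacklevel=2,
            )
            continue
        raw += row.weight * d
        used.append(row.variant_id)
    if not used:
        raise ValueError("no weight-table variant overlaps the genotype matrix")
    return PRSVector(
        sample_ids=list(genotypes.sample_ids),
        raw=raw,
        standardized=None,
        trait=weights.trait,
        n_variants_requested=len(weights),
        n_variants_used=len(used),
        variants_used=used,
    )


def standardize(prs: PRSVector, flip: bool = False) -> PRSVector:
    """Standardize to mean 0, SD 1 (population SD of the analysis sample).

    With ``flip=True`` the standardized score is negated and the
    orientation set to -1, so +1 unit means a 1 SD *decrease* in the
    genetically predicted trait.
    """
    sd = prs.raw.std()  # population SD (ddof=0) by convention
    if sd == 0:
        raise ValueError("constant raw score cannot be standardized")
    z = (prs.raw - prs.raw.mean()) / sd
    orientation = +1
    if flip:
        z = -z
        orientation = -1
    return PRSVector(
        sample_ids=prs.sample_ids,
        raw=prs.raw,
        standardized=z,
        trait=prs.trait,
        n_variants_requested=prs.n_variants_requested,
        n_variants_used=prs.n_variants_used,
        orientation=orientation,
        variants_used=list(prs.variants_used),
    )


def _score_values(prs: PRSVector) -> np.ndarray:
    return prs.standardized if prs.standardized is not None else prs.raw


def assign_factorial_groups(
    bmi_prs: PRSVector, vitd_prs: PRSVector
) -> FactorialAssignment:
    """Median-split both scores and combine into the four factorial groups.

    Values equal to or below the median count as *low*. Both scores must
    be in trait-increasing orientation; the median split is performed on
    the unflipped 25(OH)D score, so "vitD high" means genetically higher
    25(OH)D (the protective side).
    """
    if bmi_prs.sample_ids != vitd_prs.sample_ids:
        raise ValueError("sample ids of the two scores do not match")
    if vitd_prs.orientation != +1 or bmi_prs.orientation != +1:
        raise ValueError("factorial grouping requires trait-increasing scores")
    b = _score_values(bmi_prs)
    v = _score_values(vitd_prs)
    bmi_high = b > np.median(b)
    vitd_low = v <= np.median(v)
    # 0: BMI low & vitD high; 1: BMI low & vitD low;
    # 2: BMI high & vitD high; 3: BMI high & vitD low
    group = np.select(
        [~bmi_high & ~vitd_low, ~bmi_high & vitd_low, bmi_high & ~vitd_low],
        [0, 1, 2],
        default=3,
    ).astype(int)
    return FactorialAssignment(sample_ids=list(bmi_prs.sample_ids), group=group)


def prs_frame(prs: PRSVector) -> pd.DataFrame:
    """Score as a TSV-ready frame keyed by sample_id."""
    return pd.DataFrame(
        {
            "sample_id": prs.sample_ids,
            "raw": prs.raw,
            "standardized": (
                prs.standardized if prs.standardized is not None else np.nan
            ),
        }
    )
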