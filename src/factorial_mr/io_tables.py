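"""Readers and writers for the pipeline's tabular inputs and outputs.

Three kinds of input feed every analysis: per-variant weight tables
defining a polygenic risk score (PRS), genotype dosage matrices
(delimited table or VCF), and a cohort phenotype/covariate table.
Variant identity is matched by id string only — the published scores
are rsID lists, so no positional liftover is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")

#: cohort covariate columns required by the factorial MR models
PC_COLUMNS = [f"pc{i}" for i in range(1, 21)]
COHORT_COLUMNS = (
    ["sample_id", "age", "sex", "batch"]
    + PC_COLUMNS
    + ["bmi", "vitd", "draw_month", "psoriasis"]
)


class TableError(ValueError):
    """A structural or invariant violation in an input table."""


@dataclass
class WeightTable:
    """Per-variant effect alleles and per-allele weights for one PRS.

    Parameters
    ----------
    trait : str
        Label of the trait the score predicts (e.g. ``"BMI"``, ``"25OHD"``).
    entries : pandas.DataFrame
        Columns ``variant_id``, ``effect_allele``, ``other_allele``,
        ``weight``; row order is meaningful and preserved.
    """

    trait: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["variant_id", "effect_allele", "other_allele", "weight"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise TableError(f"weight table missing columns: {missing}")
        ids = self.entries["variant_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise TableError(f"duplicate variant id(s): {sorted(set(dup))}")
        w = pd.to_numeric(self.entries["weight"], errors="coerce")
        bad = self.entries.index[~np.isfinite(w)]
        if len(bad):
            raise TableError(f"non-numeric/non-finite weight at row(s) {list(bad)}")
        self.entries = self.entries.assign(weight=w.astype(float)).reset_index(drop=True)
        same = self.entries["effect_allele"] == self.entries["other_allele"]
        if same.any():
            raise TableError(
                "effect allele equals other allele for "
                f"{list(self.entries.loc[same, 'variant_id'])}"
            )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant allele labels.

    ``dosages`` holds the count of the *counted* allele in [0, 2];
    missing genotypes are NaN.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    counted_alleles: list[str]
    other_alleles: list[str]
    dosages: np.ndarray  # shape (n_samples, n_variants), float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise TableError("dosage matrix shape inconsistent with id lists")
        if len(set(self.sample_ids)) != n or len(set(self.variant_ids)) != m:
            raise TableError("sample or variant ids not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-6 or finite.max() > 2 + 1e-6):
            raise TableError("dosage outside [0, 2] beyond tolerance 1e-6")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def read_weight_table(path, trait: str = "trait", sep: str | None = None) -> WeightTable:
    """Read a delimited per-variant weight file into a :class:`WeightTable`.

    The header must name the four columns ``variant_id``, ``effect_allele``,
    ``other_allele`` and ``weight`` (case-insensitive; ``id``/``rsid``,
    ``ea``, ``oa``/``nea``, ``beta`` accepted as synonyms).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in {"variant_id", "id", "rsid", "snp"}:
            rename[col] = "variant_id"
        elif key in {"effect_allele", "ea"}:
            rename[col] = "effect_allele"
        elif key in {"other_allele", "oa", "nea"}:
            rename[col] = "other_allele"
        elif key in {"weight", "beta", "effect"}:
            rename[col] = "weight"
    df = df.rename(columns=rename)
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.strip()
    if "weight" in df.columns:
        w = pd.to_numeric(df["weight"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(w.to_numpy()))
        if len(bad):
            # +2: header line and 1-based numbering
            raise TableError(f"non-numeric weight at file row {bad[0] + 2}")
    return WeightTable(trait=trait, entries=df)


def write_weight_table(table: WeightTable, path, sep: str = "\t") -> None:
    table.entries.to_csv(path, sep=sep, index=False)


def read_genotypes(path, format: str = "delimited") -> GenotypeMatrix:
    """Read genotype dosages from a delimited table or a VCF.

    Delimited layout: samples as rows, first column ``sample_id``, one
    column per variant headed ``variant_id|counted_allele|other_allele``.
    VCF: dosage from the ``DS`` FORMAT field when present, otherwise the
    ALT-allele count of ``GT``; the counted allele is ALT. Multi-allelic
    records are skipped with a warning.
    """
    if format == "delimited":
        return _read_genotypes_delimited(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_delimited(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    variant_ids, counted, other = [], [], []
    for col in df.columns[1:]:
        parts = col.split("|")
        if len(parts) != 3:
            raise TableError(
                f"genotype column header {col!r} is not 'variant|counted|other'"
            )
        variant_ids.append(parts[0])
        counted.append(parts[1])
        other.append(parts[2])
    dosages = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    return GenotypeMatrix(sample_ids, variant_ids, counted, other, dosages)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids, counted, other, cols = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {rec.CHROM}:{rec.POS}", stacklevel=2
            )
            continue
        vid = rec.ID if rec.ID not in (None, ".") else (
            f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        )
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[col < -0.5] = np.nan  # cyvcf2 encodes missing as large negative
        else:
            gts = rec.genotype.array()  # rows: allele0, allele1, phased
            alleles = np.asarray(gts, dtype=float)[:, :2]
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
        variant_ids.append(vid)
        counted.append(rec.ALT[0])
        other.append(rec.REF)
        cols.append(col)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids, variant_ids, counted, other, dosages)


def write_genotypes(gm: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write a :class:`GenotypeMatrix` in the delimited layout."""
    headers = [
        f"{v}|{c}|{o}"
        for v, c, o in zip(gm.variant_ids, gm.counted_alleles, gm.other_alleles)
    ]
    df = pd.DataFrame(gm.dosages, columns=headers)
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_cohort(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a cohort phenotype/covariate table.

    Returns a DataFrame with the canonical columns (``sample_id``, ``age``,
    ``sex``, ``batch``, ``pc1``..``pc20``, ``bmi``, ``vitd``, ``draw_month``,
    ``psoriasis``). Missing BMI / 25(OH)D / draw month cells are allowed and
    logged; rows without a psoriasis status are dropped with a warning, and a
    psoriasis value outside {0, 1} is a hard error.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype={"sample_id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableError(f"cohort table missing columns: {missing_cols}")
    df = df[COHORT_COLUMNS].copy()
    no_status = df["psoriasis"].isna()
    if no_status.any():
        warnings.warn(
            f"dropping {int(no_status.sum())} row(s) without psoriasis status",
            stacklevel=2,
        )
        df = df.loc[~no_status]
    pso = pd.to_numeric(df["psoriasis"], errors="coerce")
    if not pso.isin([0, 1]).all():
        bad = df.loc[~pso.isin([0, 1]), "sample_id"].tolist()
        raise TableError(f"psoriasis status not in {{0,1}} for sample(s) {bad[:5]}")
    df["psoriasis"] = pso.astype(int)
    for col in ["age", "bmi", "vitd", "draw_month"] + PC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["age"] <= 0).any():
        raise TableError("non-positive age")
    if (df["bmi"].dropna() <= 0).any():
        raise TableError("non-positive BMI")
    if (df["vitd"].dropna() < 0).any():
        raise TableError("negative 25(OH)D")
    months = df["draw_month"].dropna()
    if len(months) and not months.isin(range(1, 13)).all():
        raise TableError("draw_month outside 1-12")
    for col in ("bmi", "vitd", "draw_month"):
        k = int(df[col].isna().sum())
        if k:
            logger.info("%s: %d missing", col, k)
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


@dataclass
class ResultRow:
    """One row of a result report: a named estimate with Wald 95% CI."""

    analysis: str
    term: str
    estimate: float
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    valid: bool | None = None
    extra: dict = field(default_factory=dict)


def write_results(rows: list[ResultRow], path, sep: str = "\t") -> None:
    """Serialize result rows as a TSV report.

    Full double precision is kept so downstream consumers (e.g. meta-
    analysis over per-cohort reports) can reproduce pooled quantities
    exactly; presentation rounding is the reader's job.
    """
    df = pd.DataFrame(
        [
            {
                "analysis": r.analysis,
                "term": r.term,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "valid": "" if r.valid is None else r.valid,
                **r.extra,
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
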