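"""Simulate the two study cohorts and tabulate their characteristics.

Writes a characteristics table (results/cohort_characteristics.tsv)
mirroring the usual cohort-description layout — n, prevalence, trait
means/SDs, factorial group counts — and drops the cohort phenotype and
weight tables under scratch/analysis/ for inspection. Genotype dosage
matrices are large and fully reproducible from the seed, so they are
not dumped to disk here.
"""

import pandas as pd

import factorial_mr as fm
from common import RESULTS, SCRATCH, cohort_bundle


def characterize(name: str) -> dict:
    b = cohort_bundle(name)
    cohort = b["cohort"]
    groups = fm.assign_factorial_groups(b["bmi"], b["vitd"])
    counts = groups.counts()
    row = {
        "cohort": name,
        "n": len(cohort),
        "prevalence": cohort["psoriasis"].mean(),
        "age_mean": cohort["age"].mean(),
        "bmi_mean": cohort["bmi"].mean(),
        "bmi_sd": cohort["bmi"].std(),
        "vitd_mean_raw": cohort["vitd"].mean(),
        "missing_bmi": int(cohort["bmi"].isna().sum()),
        "missing_vitd": int(cohort["vitd"].isna().sum()),
        **{f"group{g}_n": int(counts[g]) for g in range(4)},
        "true_reri": b["truth"].reri,
    }
    out = SCRATCH / name
    out.mkdir(parents=True, exist_ok=True)
    fm.write_cohort(cohort, out / "cohort.tsv")
    fm.write_weight_table(b["wb"], out / "weights_bmi.tsv")
    fm.write_weight_table(b["wv"], out / "weights_vitd.tsv")
    return row


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = pd.DataFrame([characterize("ukb"), characterize("hunt")])
    table.to_csv(RESULTS / "cohort_characteristics.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(table.to_string(index=False))
    print(
        "\nBoth cohorts were generated in additive-null mode (true RERI = 0); "
        "factorial groups split near 25% each, as expected for independent "
        "scores."
    )


if __name__ == "__main__":
    main()
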