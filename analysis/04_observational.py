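"""Traditional observational analyses of the UKB-like cohort.

Season-adjusts measured 25(OH)D, then fits (i) the continuous model —
25(OH)D per 10 nmol/l decrease, BMI per 5 kg/m^2 increase, their
cross-product, adjusted for age and sex — and (ii) the 2x2 model on
exposures dichotomized at 25 nmol/l and 27.5 kg/m^2, unadjusted and
adjusted. Complete-case counts shrink relative to the MR analyses
because measured BMI and 25(OH)D carry missing values. Writes
results/observational_continuous.tsv and results/observational_2x2.tsv.
"""

import pandas as pd

import factorial_mr as fm
from factorial_mr.observational import season_adjust
from common import RESULTS, cohort_bundle


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    b = cohort_bundle("ukb")
    cohort = b["cohort"].copy()
    adj, model = season_adjust(
        cohort["vitd"].to_numpy(float), cohort["draw_month"].to_numpy(float)
    )
    cohort["vitd_adj"] = adj
    print("season means:",
          ", ".join(f"{s}={m:.2f}" for s, m in model.season_means.items()))

    cont = fm.run_observational_continuous(cohort)
    two = fm.run_observational_2x2(cohort)

    def dump(rows, path):
        pd.DataFrame([{
            "analysis": r.analysis, "term": r.term, "estimate": r.estimate,
            "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "valid": r.valid,
        } for r in rows]).to_csv(path, sep="\t", index=False,
                                 float_format="%.5g")

    dump(cont.rows, RESULTS / "observational_continuous.tsv")
    dump(two.rows, RESULTS / "observational_2x2.tsv")
    print(f"continuous model (n = {cont.n}): "
          f"RERI = {cont.reri.estimate:.4f} "
          f"({cont.reri.ci_low:.4f} to {cont.reri.ci_high:.4f})")
    print(f"2x2 model (n = {two.n}): unadjusted RERI = "
          f"{two.reri_unadjusted.estimate:.4f}, adjusted RERI = "
          f"{two.reri.estimate:.4f}")
    print("\nThe generator ties psoriasis odds to the genetic scores only, "
          "so the observational exposure contrasts here are diluted "
          "score-trait associations; the RERI truth remains 0.")


if __name__ == "__main__":
    main()
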