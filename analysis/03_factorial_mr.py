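"""Factorial MR analyses of both simulated cohorts.

Runs the 2x2 (median-dichotomized groups) and continuous (standardized
scores + cross-product) factorial MR with the full covariate set (age,
sex, batch, 20 PCs), and additionally scales the UKB-like continuous
estimates to 5 kg/m^2 of BMI and 10 nmol/l of 25(OH)D using the
cohort's own first-stage effects. Both cohorts were generated in
additive-null mode, so the RERIs should be statistically indistinguishable
from zero. Writes results/factorial_mr_2x2.tsv and
results/factorial_mr_continuous.tsv.
"""

import pandas as pd

import factorial_mr as fm
from factorial_mr.observational import season_adjust
from common import RESULTS, cohort_bundle


def rows_to_frame(rows, cohort_name):
    recs = []
    for r in rows:
        recs.append({
            "cohort": cohort_name, "analysis": r.analysis, "term": r.term,
            "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "valid": r.valid,
        })
    return pd.DataFrame(recs)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    frames_2x2, frames_cont = [], []
    for name in ("ukb", "hunt"):
        b = cohort_bundle(name)
        rep2 = fm.run_2x2_factorial(b["cohort"], b["bmi"], b["vitd"])
        frames_2x2.append(rows_to_frame(rep2.rows, name))
        repc = fm.run_continuous_factorial(
            b["cohort"], b["bmi"], b["vitd_flipped"]
        )
        frames_cont.append(rows_to_frame(repc.rows, name))
        print(f"{name}: 2x2 RERI = {rep2.reri.estimate:.4f} "
              f"({rep2.reri.ci_low:.4f} to {rep2.reri.ci_high:.4f}); "
              f"continuous RERI = {repc.reri.estimate:.4f} "
              f"({repc.reri.ci_low:.4f} to {repc.reri.ci_high:.4f})")
        if name == "ukb":
            cohort = b["cohort"].copy()
            adj, _ = season_adjust(
                cohort["vitd"].to_numpy(float),
                cohort["draw_month"].to_numpy(float),
            )
            cohort["vitd_adj"] = adj
            fs_bmi = fm.run_diagnostics(cohort, b["bmi"], "bmi").first_stage
            fs_vitd = fm.run_diagnostics(
                cohort, b["vitd"], "vitd_adj"
            ).first_stage
            scaled = fm.scale_estimates(repc, fs_bmi.slope, abs(fs_vitd.slope))
            frames_cont.append(rows_to_frame(scaled.rows, "ukb"))
            print(f"ukb scaled (5 kg/m^2, 10 nmol/l): RERI = "
                  f"{scaled.reri.estimate:.4f} ({scaled.reri.ci_low:.4f} to "
                  f"{scaled.reri.ci_high:.4f})")
    pd.concat(frames_2x2).to_csv(RESULTS / "factorial_mr_2x2.tsv", sep="\t",
                                 index=False, float_format="%.5g")
    pd.concat(frames_cont).to_csv(RESULTS / "factorial_mr_continuous.tsv",
                                  sep="\t", index=False, float_format="%.5g")
    print("\nBoth cohorts were generated with exactly additive group odds "
          "(true RERI = 0). A nominal 95% interval still excludes 0 for "
          "about 1 cohort draw in 20; judge calibration from the coverage "
          "test suite, not a single draw.")


if __name__ == "__main__":
    main()
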