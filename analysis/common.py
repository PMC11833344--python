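"""Shared study conditions for the numbered analysis scripts.

Two synthetic cohorts stand in for the two access-restricted biobanks:
a UKB-like cohort (psoriasis prevalence 3.1%, BMI-score R^2 4.8%,
vitD-score R^2 4.6%) and a HUNT-like cohort (prevalence 9.0%, BMI-score
R^2 3.4%). Both are simulated at n = 50,000 under the additive-null
outcome mode, so every downstream RERI has a known truth of zero.
Scripts regenerate the cohorts from fixed seeds rather than passing
files around; the generator is deterministic given the seed.
"""

from pathlib import Path

import factorial_mr as fm

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"

UKB_CONFIG = fm.SimConfig(n=50_000, seed=101)
HUNT_CONFIG = fm.hunt_like(fm.SimConfig(n=50_000, seed=202))

_cache: dict = {}


def cohort_bundle(name: str):
    """Generate (once per process) a named cohort with its scores."""
    if name not in _cache:
        cfg = {"ukb": UKB_CONFIG, "hunt": HUNT_CONFIG}[name]
        gm, cohort, (wb, wv), truth = fm.generate_cohort(cfg)
        _cache[name] = {
            "config": cfg,
            "gm": gm,
            "cohort": cohort,
            "wb": wb,
            "wv": wv,
            "truth": truth,
            "bmi": fm.standardize(fm.compute_prs(gm, wb)),
            "vitd": fm.standardize(fm.compute_prs(gm, wv)),
            "vitd_flipped": fm.standardize(fm.compute_prs(gm, wv), flip=True),
        }
    return _cache[name]
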