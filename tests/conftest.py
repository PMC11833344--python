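import numpy as np
import pandas as pd
import pytest

import factorial_mr as fm


@pytest.fixture(scope="session")
def sim_additive_null():
    """One UKB-like additive-null cohort, shared across tests.

    n = 12,000 keeps the session fast while leaving the factorial fits
    well-conditioned at 3.1% prevalence.
    """
    cfg = fm.SimConfig(
        n=12_000, n_variants_bmi=80, n_variants_vitd=21, seed=2024
    )
    gm, cohort, (wb, wv), truth = fm.generate_cohort(cfg)
    return {"config": cfg, "gm": gm, "cohort": cohort, "wb": wb, "wv": wv,
            "truth": truth}


@pytest.fixture(scope="session")
def sim_scores(sim_additive_null):
    """Standardized scores recomputed from the simulated genotypes."""
    s = sim_additive_null
    bmi = fm.standardize(fm.compute_prs(s["gm"], s["wb"]))
    vitd = fm.standardize(fm.compute_prs(s["gm"], s["wv"]))
    vitd_flipped = fm.standardize(fm.compute_prs(s["gm"], s["wv"]), flip=True)
    return {"bmi": bmi, "vitd": vitd, "vitd_flipped": vitd_flipped}


@pytest.fixture()
def tiny_weight_frame():
    return pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "T"],
            "weight": [0.1, 0.2, 0.3],
        }
    )


@pytest.fixture()
def tiny_genotypes():
    return fm.GenotypeMatrix(
        sample_ids=["s1", "s2"],
        variant_ids=["rs1", "rs2", "rs3"],
        counted_alleles=["A", "C", "G"],
        other_alleles=["G", "T", "T"],
        dosages=np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0]]),
    )
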