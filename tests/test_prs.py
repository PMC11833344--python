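import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import factorial_mr as fm


class TestComputePrs:
    def test_weighted_allele_sum(self, tiny_genotypes, tiny_weight_frame):
        wt = fm.WeightTable(trait="BMI", entries=tiny_weight_frame)
        prs = fm.compute_prs(tiny_genotypes, wt)
        # s1: 0*0.1 + 1*0.2 + 2*0.3 = 0.8
        assert prs.raw[0] == pytest.approx(0.8)
        assert prs.n_variants_used == 3
        assert prs.n_variants_requested == 3

    def test_counted_on_other_allele_flips_dosage(self):
        gm = fm.GenotypeMatrix(
            sample_ids=["s1"], variant_ids=["rs1"],
            counted_alleles=["G"], other_alleles=["A"],  # counted = other allele
            dosages=np.array([[2.0]]),
        )
        wt = fm.WeightTable(
            trait="x",
            entries=pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele": ["A"],
                 "other_allele": ["G"], "weight": [0.5]}
            ),
        )
        prs = fm.compute_prs(gm, wt)
        assert prs.raw[0] == pytest.approx(0.5 * (2 - 2))

    def test_absent_variant_counted_in_n_used(self, tiny_genotypes, tiny_weight_frame):
        extra = pd.concat(
            [tiny_weight_frame,
             pd.DataFrame({"variant_id": ["rs999"], "effect_allele": ["A"],
                           "other_allele": ["T"], "weight": [1.0]})],
            ignore_index=True,
        )
        wt = fm.WeightTable(trait="x", entries=extra)
        prs = fm.compute_prs(tiny_genotypes, wt)
        assert prs.n_variants_requested == 4
        assert prs.n_variants_used == 3

    def test_allele_mismatch_skipped_with_warning(self, tiny_genotypes):
        wt = fm.WeightTable(
            trait="x",
            entries=pd.DataFrame(
                {"variant_id": ["rs1", "rs2"], "effect_allele": ["C", "C"],
                 "other_allele": ["T", "T"], "weight": [1.0, 1.0]}
            ),
        )
        with pytest.warns(UserWarning, match="allele mismatch"):
            prs = fm.compute_prs(tiny_genotypes, wt)
        assert prs.n_variants_used == 1  # only rs2 matches

    def test_zero_overlap_is_error(self, tiny_genotypes):
        wt = fm.WeightTable(
            trait="x",
            entries=pd.DataFrame(
                {"variant_id": ["nope"], "effect_allele": ["A"],
                 "other_allele": ["G"], "weight": [1.0]}
            ),
        )
        with pytest.raises(ValueError, match="no weight-table variant"):
            fm.compute_prs(tiny_genotypes, wt)

    def test_missing_dosage_mean_imputed(self):
        gm = fm.GenotypeMatrix(
            sample_ids=["s1", "s2", "s3"], variant_ids=["rs1"],
            counted_alleles=["A"], other_alleles=["G"],
            dosages=np.array([[np.nan], [1.0], [2.0]]),
        )
        wt = fm.WeightTable(
            trait="x",
            entries=pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele": ["A"],
                 "other_allele": ["G"], "weight": [1.0]}
            ),
        )
        prs = fm.compute_prs(gm, wt)
        assert prs.raw[0] == pytest.approx(1.5)  # mean of non-missing

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.1, 10), perm_seed=st.integers(0, 10_000))
    def test_linearity_and_permutation_invariance(self, scale, perm_seed):
        rng = np.random.default_rng(17)
        n, m = 8, 5
        gm = fm.GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            variant_ids=[f"rs{j}" for j in range(m)],
            counted_alleles=["A"] * m,
            other_alleles=["G"] * m,
            dosages=rng.integers(0, 3, size=(n, m)).astype(float),
        )
        frame = pd.DataFrame(
            {
                "variant_id": gm.variant_ids,
                "effect_allele": ["A"] * m,
                "other_allele": ["G"] * m,
                "weight": rng.normal(size=m),
            }
        )
        wt = fm.WeightTable(trait="x", entries=frame)
        base = fm.compute_prs(gm, wt)
        scaled_wt = fm.WeightTable(
            trait="x", entries=frame.assign(weight=frame["weight"] * scale)
        )
        np.testing.assert_allclose(
            fm.compute_prs(gm, scaled_wt).raw, base.raw * scale, rtol=1e-12
        )
        perm = np.random.default_rng(perm_seed).permutation(n)
        gm_p = fm.GenotypeMatrix(
            sample_ids=[gm.sample_ids[i] for i in perm],
            variant_ids=gm.variant_ids,
            counted_alleles=gm.counted_alleles,
            other_alleles=gm.other_alleles,
            dosages=gm.dosages[perm],
        )
        np.testing.assert_allclose(fm.compute_prs(gm_p, wt).raw, base.raw[perm])


class TestStandardize:
    def _prs(self, raw):
        return fm.PRSVector(
            sample_ids=[f"s{i}" for i in range(len(raw))],
            raw=np.asarray(raw, float), standardized=None, trait="x",
            n_variants_requested=1, n_variants_used=1,
        )

    def test_mean_zero_sd_one_population_convention(self):
        z = fm.standardize(self._prs([1.0, 2.0, 3.0])).standardized
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std() == pytest.approx(1, abs=1e-12)  # ddof=0
        np.testing.assert_allclose(z, np.array([-1, 0, 1]) * np.sqrt(1.5))

    def test_flip_negates(self):
        a = fm.standardize(self._prs([1.0, 2.0, 3.0]))
        b = fm.standardize(self._prs([1.0, 2.0, 3.0]), flip=True)
        np.testing.assert_allclose(b.standardized, -a.standardized)
        assert b.orientation == -1

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fm.standardize(self._prs([2.0, 2.0, 2.0]))


class TestFactorialGroups:
    def _vec(self, values, trait="x"):
        return fm.PRSVector(
            sample_ids=[f"s{i}" for i in range(len(values))],
            raw=np.asarray(values, float), standardized=None, trait=trait,
            n_variants_requested=1, n_variants_used=1,
        )

    def test_group_coding(self):
        # BMI below median & vitD above median -> reference group 0
        bmi = self._vec([1.0, 1.0, 3.0, 3.0])
        vitd = self._vec([3.0, 1.0, 3.0, 1.0])
        groups = fm.assign_factorial_groups(bmi, vitd)
        assert groups.group.tolist() == [0, 1, 2, 3]

    def test_value_equal_to_median_is_low(self):
        bmi = self._vec([1.0, 2.0, 3.0])  # median 2 -> "low" includes 2
        vitd = self._vec([3.0, 2.0, 1.0])
        groups = fm.assign_factorial_groups(bmi, vitd)
        assert groups.group[1] in (0, 1)  # middle BMI value classified low

    def test_even_n_distinct_values_split_exactly(self):
        rng = np.random.default_rng(3)
        n = 4000
        bmi = self._vec(rng.normal(size=n))
        vitd = self._vec(rng.normal(size=n))
        groups = fm.assign_factorial_groups(bmi, vitd)
        counts = groups.counts()
        assert counts.sum() == n
        b = groups.group
        assert ((b == 2) | (b == 3)).sum() == n // 2  # BMI high exactly half
        assert ((b == 1) | (b == 3)).sum() == n // 2  # vitD low exactly half
        # independent scores: near-equal quadrants
        assert np.all(np.abs(counts - n / 4) < 4 * np.sqrt(n) / 2)

    def test_sample_mismatch_rejected(self):
        bmi = self._vec([1.0, 2.0])
        vitd = fm.PRSVector(
            sample_ids=["a", "b"], raw=np.array([1.0, 2.0]),
            standardized=None, trait="y", n_variants_requested=1,
            n_variants_used=1,
        )
        with pytest.raises(ValueError, match="sample ids"):
            fm.assign_factorial_groups(bmi, vitd)
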