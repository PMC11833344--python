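import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import factorial_mr as fm
from factorial_mr.glm import build_design


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            # dichotomized single-association and combined-group tables
            ((435, 11666, 10669, 339125), 1.19),
            ((273, 6411, 5287, 196501), 1.58),
            ((5382, 142624, 5287, 196501), 1.40),
        ],
    )
    def test_published_contingency_tables(self, cells, expected):
        est = fm.odds_ratio_2x2(*cells)
        assert round(est.or_value, 2) == expected

    def test_equal_case_proportions_give_unity(self):
        est = fm.odds_ratio_2x2(10, 90, 30, 270)
        assert est.or_value == pytest.approx(1.0)

    def test_woolf_interval(self):
        est = fm.odds_ratio_2x2(20, 80, 10, 90)
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        assert est.se_log_or == pytest.approx(se)
        assert est.ci_low == pytest.approx(est.or_value * np.exp(-1.96 * se))

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fm.odds_ratio_2x2(0, 10, 5, 10)


class TestReriFromOrs:
    def test_null_is_exactly_zero(self):
        assert fm.reri_from_ors(1, 1, 1) == 0.0

    def test_arithmetic(self):
        assert fm.reri_from_ors(2.0, 1.5, 1.3) == pytest.approx(0.2)

    def test_published_combined_groups_round_to_003(self):
        ref = (5287, 196501)
        or01 = fm.odds_ratio_2x2(162, 5255, *ref).or_value
        or10 = fm.odds_ratio_2x2(5382, 142624, *ref).or_value
        or11 = fm.odds_ratio_2x2(273, 6411, *ref).or_value
        assert round(fm.reri_from_ors(or11, or10, or01), 2) == 0.03

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fm.reri_from_ors(1.0, -0.5, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        or10=st.floats(0.5, 3), or01=st.floats(0.5, 3),
        base=st.floats(1.0, 3), bump=st.floats(0.01, 2),
    )
    def test_monotone_in_or11(self, or10, or01, base, bump):
        assert fm.reri_from_ors(base + bump, or10, or01) > fm.reri_from_ors(
            base, or10, or01
        )


class TestAdditiveTerm:
    def test_published_component_product(self):
        b = np.log([1.03, 1.18, 1.00])
        assert round(fm.additive_term(*b), 2) == 1.22

    def test_zero_coefficients(self):
        assert fm.additive_term(0, 0, 0) == 1.0

    def test_is_product_of_component_ors(self):
        assert fm.additive_term(np.log(2), np.log(3), np.log(0.5)) == pytest.approx(3.0)


class TestValidity:
    @pytest.mark.parametrize(
        "ors, expected",
        [
            ((1.05, 1.07, 1.12), True),
            ((0.96, 1.07, 1.06), False),
            ((1.0, 1.2, 1.3), False),  # strictly above 1 required
        ],
    )
    def test_all_above_one_rule(self, ors, expected):
        assert fm.check_validity(*ors) is expected


class TestReriFromFit:
    def test_zero_coefficients_give_zero_symmetric_ci(self):
        cov = np.eye(3) * 0.04
        res = fm.reri_from_coefficients(np.zeros(3), cov, design_2x2=True)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_identity_with_component_ors(self, sim_additive_null, sim_scores):
        report = fm.run_2x2_factorial(
            sim_additive_null["cohort"], sim_scores["bmi"], sim_scores["vitd"],
            covariates=(),
        )
        r = report.reri
        assert r.estimate == pytest.approx(
            fm.reri_from_ors(r.or11, r.or10, r.or01), abs=1e-10
        )

    def test_saturated_fit_reproduces_published_reri(self):
        # individual-level reconstruction of the combined four-group table
        counts = {0: (5287, 196501), 1: (162, 5255), 2: (5382, 142624),
                  3: (273, 6411)}
        rows_g, rows_y = [], []
        for g, (cases, noncases) in counts.items():
            rows_g += [g] * (cases + noncases)
            rows_y += [1] * cases + [0] * noncases
        g = np.asarray(rows_g)
        y = np.asarray(rows_y, dtype=float)
        X = np.column_stack(
            [np.ones_like(y), (g == 1).astype(float), (g == 2).astype(float),
             (g == 3).astype(float)]
        )
        fit = fm.fit_logistic(X, y, names=["intercept", "g1", "g2", "g3"])
        res = fm.reri_from_fit(fit, ("g1", "g2", "g3"), design_2x2=True)
        assert round(res.estimate, 2) == 0.03

    def test_continuous_contrast_components(self):
        b = np.array([np.log(1.5), np.log(1.2), 0.0])
        res = fm.reri_from_coefficients(
            b, np.eye(3) * 1e-4, design_2x2=False, contrast=(1.0, 1.0)
        )
        # zero cross-product: RERI = (OR1-1)(OR2-1)
        assert res.estimate == pytest.approx(0.5 * 0.2, abs=1e-12)

    def test_missing_term_raises(self, sim_additive_null, sim_scores):
        report = fm.run_2x2_factorial(
            sim_additive_null["cohort"], sim_scores["bmi"], sim_scores["vitd"],
            covariates=(),
        )
        with pytest.raises(KeyError):
            fm.reri_from_fit(report.fit, ("nope", "group2", "group3"))

    def test_small_bootstrap_warns(self):
        rng = np.random.default_rng(0)
        n = 2000
        x1 = rng.binomial(1, 0.5, n).astype(float)
        x2 = rng.binomial(1, 0.5, n).astype(float)
        eta = -2 + 0.4 * x1 + 0.3 * x2
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), x1 * (1 - x2), x2 * (1 - x1), x1 * x2])
        # columns coded as mutually exclusive group indicators
        names = ["intercept", "g2", "g1", "g3"]
        fit = fm.fit_logistic(X, y, names=names)
        with pytest.warns(UserWarning, match="n_boot"):
            fm.reri_from_fit(
                fit, ("g1", "g2", "g3"), method="bootstrap", n_boot=150,
                seed=1, refit=(X, y),
            )


class TestMetaFixed:
    def test_two_identical_studies(self):
        res = fm.meta_fixed([0.4, 0.4], [0.1, 0.1])
        assert res.estimate == pytest.approx(0.4)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))
        np.testing.assert_allclose(res.weights, [0.5, 0.5])

    def test_symmetric_inputs_pool_to_midpoint(self):
        res = fm.meta_fixed([0.0, 2.0], [0.3, 0.3])
        assert res.estimate == pytest.approx(1.0)

    def test_three_studies_match_brute_force(self):
        est = [0.1, -0.2, 0.35]
        se = [0.05, 0.12, 0.4]
        res = fm.meta_fixed(est, se)
        w = [1 / s**2 for s in se]
        brute = sum(wi * ei for wi, ei in zip(w, est)) / sum(w)
        assert res.estimate == pytest.approx(brute, abs=1e-12)
        assert res.se <= min(se)
        assert res.weights.sum() == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fm.meta_fixed([0.1, 0.2], [0.1])
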