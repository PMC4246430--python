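"""NB GLM fitting, LRT/Wald testing, BH adjustment and fold changes.

The in-package fitter is cross-checked against statsmodels GLM (an
independent IRLS implementation) at fixed dispersion.
"""

import numpy as np
import pytest

from sagesac.differential_expression import (
    DEFAULT_CONTRASTS,
    bh_adjust,
    fit_nb_glm,
    fold_change,
    lrt_overall,
    nb_loglik,
    pairwise_contrast,
    run_de,
)

from conftest import make_count_matrix

DAYS5 = ["E13"] * 3 + ["E15"] * 3 + ["E17"] * 3 + ["E19"] * 3 + ["E21"] * 3


class TestFit:
    def test_constant_counts_equal_means_zero_lrt(self):
        y = [7] * 15
        fit = fit_nb_glm(y, DAYS5)
        assert np.allclose(fit.mu, 7.0, rtol=1e-6)
        stat, p = lrt_overall(fit)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_matches_statsmodels_glm_at_fixed_phi(self, rng):
        import statsmodels.api as sm

        y = rng.negative_binomial(10, 10 / (10 + 100), size=15)
        off = np.log(rng.uniform(0.5, 2.0, size=15))
        fit = fit_nb_glm(y, DAYS5, offsets=off)
        X = np.zeros((15, 5))
        for i, d in enumerate(sorted(set(DAYS5))):
            X[np.array(DAYS5) == d, i] = 1
        m = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=fit.phi), offset=off
        ).fit()
        assert np.allclose(fit.beta, m.params, atol=1e-6)
        assert fit.loglik == pytest.approx(m.llf, abs=1e-6)

    def test_poisson_data_phi_near_floor(self, rng):
        hits = 0
        for _ in range(20):
            y = rng.poisson(200, size=15)
            fit = fit_nb_glm(y, DAYS5)
            hits += fit.phi < 1e-2
        assert hits >= 15  # phi collapses toward the floor without overdispersion

    def test_parameter_recovery_nb(self, rng):
        """mu=(50..800) doubling across days, phi=0.1: estimated ln-means
        within 3 SE of truth in the large majority of replicates."""
        mu_true = np.repeat([50, 100, 200, 400, 800], 3).astype(float)
        r = 10.0
        n_ok, n_rep = 0, 60
        for _ in range(n_rep):
            y = rng.negative_binomial(r, r / (r + mu_true))
            fit = fit_nb_glm(y, DAYS5)
            se = np.sqrt(fit.beta_var)
            ok = np.abs(fit.beta - np.log([50, 100, 200, 400, 800])) <= 3 * se
            n_ok += ok.all()
        assert n_ok / n_rep >= 0.9

    def test_offsets_contract(self, rng):
        """Doubling one sample's counts together with its scale factor
        leaves the fit unchanged."""
        y = rng.negative_binomial(10, 10 / 110, size=15).astype(float)
        factors = np.ones(15)
        fit1 = fit_nb_glm(y, DAYS5, offsets=np.log(factors))
        y2, f2 = y.copy(), factors.copy()
        y2[4] = round(y2[4] * 2)
        f2[4] *= 2
        # integer rounding: rebuild the count so mu doubles exactly
        y2[4] = y[4] * 2
        fit2 = fit_nb_glm(y2, DAYS5, offsets=np.log(f2))
        # means agree closely (dispersion re-estimated on slightly different data)
        assert np.allclose(fit1.beta, fit2.beta, atol=0.05)

    def test_all_zero_gene_degenerate(self):
        fit = fit_nb_glm([0] * 15, DAYS5)
        assert fit.degenerate
        assert np.isnan(lrt_overall(fit)[1])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_nb_glm([1, -2, 3], ["E13", "E13", "E15"])
        with pytest.raises(ValueError):
            fit_nb_glm([1, 2], ["E13", "E13"])  # single day


class TestLRT:
    def test_strong_effect_detected(self, rng):
        """4-fold step at mu=100, phi=0.1: the asymptotic chi-square LRT
        gives p < 1e-4 in nearly all replicates; the small-sample F
        reference (default) still detects at p < 0.01."""
        mu = np.repeat([100, 100, 400, 400, 400], 3).astype(float)
        r = 10.0
        tiny_chi2 = small_f = 0
        for _ in range(50):
            y = rng.negative_binomial(r, r / (r + mu))
            fit = fit_nb_glm(y, DAYS5)
            tiny_chi2 += lrt_overall(fit, method="chi2")[1] < 1e-4
            small_f += lrt_overall(fit)[1] < 1e-2
        assert tiny_chi2 >= 45
        assert small_f >= 42

    def test_likelihood_exceeds_null(self, rng):
        y = rng.negative_binomial(5, 5 / 55, size=15)
        fit = fit_nb_glm(y, DAYS5)
        assert fit.loglik >= fit.null_loglik - 1e-8


class TestBH:
    def test_hand_computed_stepup(self):
        q, sig = bh_adjust([0.01, 0.02, 0.03], level=0.05)
        assert np.allclose(q, [0.03, 0.03, 0.03])
        assert sig.all()

    def test_all_ones(self):
        q, sig = bh_adjust([1.0, 1.0, 1.0])
        assert np.allclose(q, 1.0) and not sig.any()

    def test_nan_excluded(self):
        q, sig = bh_adjust([0.001, np.nan, 0.5])
        assert np.isnan(q[1]) and not sig[1] and sig[0]

    def test_q_monotone_in_p_ranking(self, rng):
        p = rng.random(200)
        q, _ = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestContrasts:
    def test_equal_means_null_contrast(self):
        fit = fit_nb_glm([9] * 15, DAYS5)
        lfc, p = pairwise_contrast(fit, "E13", "E17")
        assert lfc == pytest.approx(0.0, abs=1e-8)
        assert p > 0.9

    def test_wald_vs_two_day_lrt_order_of_magnitude(self, rng):
        """Wald p agrees with an LRT on the two-day submodel within an
        order of magnitude."""
        agree = 0
        for _ in range(40):
            mu = np.repeat([100, 250], 3).astype(float)
            y = rng.negative_binomial(10, 10 / (10 + mu))
            days2 = ["E13"] * 3 + ["E17"] * 3
            fit = fit_nb_glm(y, days2)
            _, p_w = pairwise_contrast(fit, "E13", "E17")
            _, p_l = lrt_overall(fit)
            if p_w > 0 and p_l > 0:
                agree += abs(np.log10(p_w) - np.log10(p_l)) <= 1.0
        assert agree >= 36

    def test_sign_convention_later_minus_earlier(self, rng):
        mu = np.repeat([50, 50, 50, 50, 400], 3).astype(float)
        y = rng.negative_binomial(10, 10 / (10 + mu))
        fit = fit_nb_glm(y, DAYS5)
        lfc, _ = pairwise_contrast(fit, "E17", "E21")
        assert lfc > 0  # up-regulation toward hatch is positive


class TestFoldChange:
    def test_arithmetic(self):
        assert fold_change(1.0, 1.0) == 1.0
        assert fold_change(2.0, 1400.0) == pytest.approx(700.0)
        assert fold_change(0.0, 5.0) == np.inf

    def test_ranking_fixture(self, rng):
        means_a = rng.uniform(1, 10, size=10)
        means_b = rng.uniform(1, 10, size=10)
        ratios = [fold_change(a, b) for a, b in zip(means_a, means_b)]
        assert np.argsort(ratios).tolist() == np.argsort(means_b / means_a).tolist()


def test_run_de_table_shape(rng):
    mu = np.array([[100] * 15, [50] * 6 + [400] * 9], dtype=float)
    y = rng.negative_binomial(10, 10 / (10 + mu))
    cm = make_count_matrix(y, DAYS5, genes=["flat", "step"])
    import pandas as pd

    factors = pd.Series(1.0, index=cm.samples, name="scale_factor")
    table = run_de(cm, factors)
    assert list(table.index) == ["flat", "step"]
    assert table.loc["step", "pvalue"] < table.loc["flat", "pvalue"]
    for a, b in DEFAULT_CONTRASTS:
        assert f"lfc_{a}_{b}" in table.columns
        assert f"q_{a}_{b}" in table.columns
    assert (table["qvalue"] >= table["pvalue"] - 1e-12).all()
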