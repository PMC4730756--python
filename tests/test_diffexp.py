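"""Dispersion model, both NB test engines, BH, and the consensus rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from ganglimark import diffexp
from ganglimark.diffexp import (
    bh_adjust,
    consensus_flags,
    estimate_gene_dispersion,
    exact_test_all_splits,
    fit_dispersion_trend,
    nb_exact_test,
    nb_glm_lrt,
    nb_glm_lrt_matrix,
    shrink_dispersions,
)


# ---------------------------------------------------------------------------
# dispersion


class TestGeneDispersion:
    def test_poisson_row_estimates_near_zero(self, rng):
        y = rng.poisson(100, size=60)
        labels = np.repeat(["a", "b"], 30)
        alpha = estimate_gene_dispersion(y, np.ones(60), labels)
        assert alpha <= 0.01

    def test_nb_row_recovers_dispersion(self, rng):
        a_true = 0.4
        r = 1 / a_true
        y = rng.negative_binomial(r, r / (r + 100), size=60)
        labels = np.repeat(["a", "b"], 30)
        alpha = estimate_gene_dispersion(y, np.ones(60), labels)
        assert 0.2 <= alpha <= 0.7

    def test_profile_likelihood_is_maximised(self, rng):
        # returned alpha beats a 50-point grid (within numerical slack)
        y = rng.negative_binomial(5, 5 / 55.0, size=12)
        s = rng.uniform(0.7, 1.4, 12)
        labels = np.repeat(["a", "b", "c"], 4)
        alpha = estimate_gene_dispersion(y, s, labels)
        group_idx = [np.flatnonzero(labels == g) for g in "abc"]
        best = diffexp._cr_pll_matrix(
            np.log(np.array([alpha])), y[None, :].astype(float), s, group_idx
        )[0]
        grid = np.exp(np.linspace(np.log(1e-8), np.log(10), 50))
        for a in grid:
            val = diffexp._cr_pll_matrix(
                np.log(np.array([a])), y[None, :].astype(float), s, group_idx
            )[0]
            assert best >= val - 1e-6

    def test_all_zero_row_is_nan(self):
        labels = np.repeat(["a", "b"], 3)
        assert np.isnan(estimate_gene_dispersion(np.zeros(6), np.ones(6), labels))


class TestDispersionTrend:
    def test_noiseless_trend_recovered_exactly(self):
        mu = np.linspace(5, 500, 50)
        alphas = 0.02 + 3.0 / mu
        a0, a1 = fit_dispersion_trend(mu, alphas)
        assert a0 == pytest.approx(0.02, abs=1e-6)
        assert a1 == pytest.approx(3.0, abs=1e-6)

    def test_constant_dispersion_gives_flat_trend(self):
        mu = np.linspace(5, 500, 40)
        a0, a1 = fit_dispersion_trend(mu, np.full(40, 0.1))
        assert a0 == pytest.approx(0.1, abs=1e-6)
        assert a1 == pytest.approx(0.0, abs=1e-4)

    def test_noisy_trend_recovered_within_25_percent(self, rng):
        mu = rng.lognormal(4.6, 1.5, 2000)
        true = 0.05 + 2.0 / mu
        noisy = true * rng.chisquare(10, 2000) / 10
        a0, a1 = fit_dispersion_trend(mu, noisy)
        assert a0 == pytest.approx(0.05, rel=0.25)
        assert a1 == pytest.approx(2.0, rel=0.25)

    def test_too_few_genes_is_an_error(self):
        with pytest.raises(ValueError, match="10 genes"):
            fit_dispersion_trend(np.arange(1, 6), np.full(5, 0.1))


class TestShrinkage:
    def test_on_trend_is_a_fixed_point(self):
        mu = np.array([10.0, 100.0])
        trend = (0.05, 2.0)
        raw = 0.05 + 2.0 / mu
        star = shrink_dispersions(raw, trend, mu, residual_df=10, d0=10)
        assert np.allclose(star, raw)

    def test_limits_return_raw_and_trend(self):
        mu = np.array([50.0])
        raw = np.array([0.4])
        trend_val = 0.05 + 2.0 / 50
        near_raw = shrink_dispersions(raw, (0.05, 2.0), mu, 10, d0=1e-12)
        near_trend = shrink_dispersions(raw, (0.05, 2.0), mu, 10, d0=1e12)
        assert near_raw[0] == pytest.approx(0.4, rel=1e-6)
        assert near_trend[0] == pytest.approx(trend_val, rel=1e-6)

    def test_betweenness_holds_for_random_genes(self, rng):
        mu = rng.lognormal(4, 1.5, 1000)
        raw = rng.lognormal(-3, 1.0, 1000)
        star = shrink_dispersions(raw, (0.05, 2.0), mu, 10, d0=10)
        trend_val = 0.05 + 2.0 / mu
        lo = np.minimum(raw, trend_val)
        hi = np.maximum(raw, trend_val)
        assert np.all(star >= lo * (1 - 1e-9)) and np.all(star <= hi * (1 + 1e-9))

    def test_nan_raw_takes_trend(self):
        star = shrink_dispersions(np.array([np.nan]), (0.1, 0.0),
                                  np.array([50.0]), 10)
        assert star[0] == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# engine 1: conditional exact test


def oracle_all_splits(total, n_high, n_low, alpha, mu=7.3):
    """Brute-force convolution: explicit NB pmf products normalised over
    all splits of the total, then literal two-sided summation."""
    x = np.arange(total + 1)
    rh, rl = n_high / alpha, n_low / alpha
    ph = nbinom.pmf(x, rh, rh / (rh + n_high * mu))
    pl = nbinom.pmf(total - x, rl, rl / (rl + n_low * mu))
    probs = ph * pl
    probs = probs / probs.sum()
    out = np.empty(total + 1)
    for xi in range(total + 1):
        out[xi] = probs[probs <= probs[xi] * (1 + 1e-7)].sum()
    return np.minimum(out, 1.0)


class TestExactTest:
    def test_balanced_mode_has_p_one(self):
        # observed split at the conditional mode sums every outcome
        p = nb_exact_test([5, 5, 5], [5, 5, 5], 0.2, np.ones(3), np.ones(3))
        assert p == pytest.approx(1.0)

    def test_poisson_limit_equals_binomial_test(self):
        total = 20
        probs = binom.pmf(np.arange(total + 1), total, 0.5)
        expected = np.array(
            [probs[probs <= probs[x] * (1 + 1e-7)].sum() for x in range(total + 1)]
        )
        ours = exact_test_all_splits(total, 3, 3, 1e-8)
        assert np.abs(ours - expected).max() < 1e-6

    @pytest.mark.parametrize("alpha", [0.05, 0.4])
    @pytest.mark.parametrize("total", [1, 7, 33, 200])
    def test_matches_convolution_oracle(self, total, alpha):
        ours = exact_test_all_splits(total, 3, 3, alpha)
        theirs = oracle_all_splits(total, 3, 3, alpha)
        assert np.abs(ours - theirs).max() < 1e-10

    def test_oracle_mean_invariance(self):
        # the conditional law is free of the nuisance mean
        a = oracle_all_splits(40, 3, 3, 0.3, mu=2.0)
        b = oracle_all_splits(40, 3, 3, 0.3, mu=50.0)
        assert np.allclose(a, b, atol=1e-12)

    def test_size_factor_rescaling_uses_common_library(self):
        # counts 5 at factor 0.5 rescale to the same effective counts as
        # counts 10 at factor 1, so the split is balanced and p = 1
        p_skew = nb_exact_test([5, 5, 5], [10, 10, 10], 0.1,
                               np.full(3, 0.5), np.ones(3))
        assert p_skew == pytest.approx(1.0, rel=1e-6)

    def test_negative_alpha_is_an_error(self):
        with pytest.raises(ValueError):
            nb_exact_test([1, 2], [3, 4], -0.1, np.ones(2), np.ones(2))


# ---------------------------------------------------------------------------
# engine 2: NB GLM LRT


class TestGlmLrt:
    def test_identical_counts_give_p_one(self):
        y = np.full(6, 50)
        mask = np.array([True] * 3 + [False] * 3)
        p = nb_glm_lrt(y, mask, np.ones(6), 0.1)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_deviance_nonnegative_over_random_rows(self, rng):
        Y = rng.negative_binomial(5, 5 / 35.0, size=(1000, 10)).astype(float)
        mask = np.array([True] * 5 + [False] * 5)
        _, D = nb_glm_lrt_matrix(Y, mask, np.ones(10), np.full(1000, 0.2))
        assert np.all(D >= 0)

    def test_coefficients_match_statsmodels(self, rng):
        import statsmodels.api as sm

        mask = np.array([True] * 5 + [False] * 5)
        X = np.column_stack([np.ones(10), mask.astype(float)])
        s = rng.uniform(0.6, 1.5, 10)
        for _ in range(20):
            alpha = float(rng.uniform(0.05, 0.5))
            mu = rng.uniform(20, 200)
            fc = rng.uniform(0.5, 2.0)
            y = rng.negative_binomial(
                1 / alpha, 1 / (1 + alpha * mu * np.where(mask, fc, 1.0))
            ).astype(float)
            if y.sum() == 0 or y[mask].sum() == 0 or y[~mask].sum() == 0:
                continue
            beta, _, conv = diffexp._irls_nb(
                y[None, :], X, np.log(s), np.array([alpha])
            )
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(s),
            ).fit(tol=1e-12)
            assert conv[0]
            assert np.abs(beta[0] - model.params).max() < 1e-6

    def test_extreme_group_zero_converges(self):
        y = np.array([0, 0, 0, 40, 50, 60], dtype=float)
        mask = np.array([True] * 3 + [False] * 3)
        p = nb_glm_lrt(y, mask, np.ones(6), 0.1)
        assert 0 < p < 1e-4


# ---------------------------------------------------------------------------
# BH and consensus


class TestBH:
    def test_single_p_is_its_own_q(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_stepped_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.04, 0.05]))
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_ties_stay_at_common_value(self):
        q = bh_adjust(np.full(7, 0.2))
        assert np.allclose(q, 0.2)

    def test_nan_passthrough_and_m_counting(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(q[1])
        # m = 2: q = (0.02, 0.02)
        assert np.allclose(q[[0, 2]], [0.02, 0.02])

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    @settings(max_examples=50)
    def test_matches_statsmodels_and_inflates(self, ps):
        from statsmodels.stats.multitest import multipletests

        p = np.array(ps)
        q = bh_adjust(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)
        assert np.all(q >= p - 1e-15)


class TestConsensus:
    def test_requires_both_engines(self):
        flags = consensus_flags(
            np.array([0.01]), np.array([0.2]), np.array([1.0])
        )
        assert not flags[0]

    def test_boundary_is_inclusive(self):
        flags = consensus_flags(
            np.array([0.05]), np.array([0.05]), np.array([0.5])
        )
        assert flags[0]

    def test_requires_positive_fold_change(self):
        flags = consensus_flags(
            np.array([0.001]), np.array([0.001]), np.array([-2.0])
        )
        assert not flags[0]

    def test_nan_never_passes(self):
        flags = consensus_flags(
            np.array([0.01]), np.array([np.nan]), np.array([1.0])
        )
        assert not flags[0]

    def test_consensus_subset_of_each_engine(self, default_run):
        for de in default_run.de_by_grouping.values():
            cons = de["consensus"].to_numpy()
            assert np.all(de["q_exact"].to_numpy()[cons] <= 0.05)
            assert np.all(de["q_glm"].to_numpy()[cons] <= 0.05)
            assert np.all(de["log2fc"].to_numpy()[cons] > 0)


# ---------------------------------------------------------------------------
# power and calibration properties


def _small_sim(log2fc, seed=5):
    from ganglimark.simulate import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(
        n_genes=800,
        n_planted_per_grouping={"N,P": 40},
        planted_log2fc_min=log2fc,
        seed=seed,
    )
    return simulate_experiment(cfg)


def test_consensus_power_monotone_in_effect_size():
    from ganglimark import normalize

    rates = []
    for fc in [0.5, 1.0, 2.0, 3.0]:
        cm, sd, ga, truth = _small_sim(fc)
        sf = normalize.size_factors_median_of_ratios(cm)
        sft = normalize.tmm_factors(cm)
        disp = diffexp.fit_dispersion_model(cm, sf.factors, sd)
        de = diffexp.de_for_grouping(
            cm, sd, frozenset(["N", "P"]), disp, sf.factors, sft.factors
        )
        planted = [g for g in truth.marker_truth]
        rates.append(de.loc[planted, "consensus"].mean())
    assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.9
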