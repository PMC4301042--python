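import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from seedperf.inference import (
    InferenceError,
    fit_binomial_glmm,
    fit_gaussian_lmm,
    holm_adjust,
    ls_means,
    shaffer_adjust,
    shaffer_attainable,
    shaffer_multipliers,
    species_inclusion,
    tukey_shaffer,
    _REMLProfile,
    _design,
    _LOG_LAMBDA_GRID,
)
from seedperf.synthetic import simulate_binomial_category, simulate_gaussian_category

from .oracles import dense_gls_reml, shaffer_multipliers_bruteforce


class TestGaussianLMM:
    def test_boundary_matches_ols(self, rng):
        """Data with no subplot effect: the REML fit collapses to OLS."""
        df = simulate_gaussian_category(
            {"A": 0.2, "B": 0.3}, {"A": 60, "B": 60}, 30, sigma_u=0.0, sigma_e=0.2,
            rng=rng,
        )
        fit = fit_gaussian_lmm(df["y"], df["species"], df["subplot_id"])
        import statsmodels.api as sm

        X = np.column_stack(
            [np.ones(len(df)), (df["species"] == "B").astype(float)]
        )
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        if fit.sigma_u2 == 0.0:
            np.testing.assert_allclose(fit.beta, ols.params, atol=1e-6)
        else:
            # REML picked up a small spurious variance: close to OLS but
            # not identical (GLS downweights crowded subplots slightly)
            np.testing.assert_allclose(fit.beta, ols.params, atol=0.02)

    def test_matches_dense_gls_oracle(self, rng):
        """Small instance vs a dense-matrix GLS + grid-search oracle."""
        df = simulate_gaussian_category(
            {"A": 0.1, "B": 0.35, "C": 0.2}, {"A": 15, "B": 15, "C": 10}, 8,
            sigma_u=0.1, sigma_e=0.2, rng=rng,
        )
        fit = fit_gaussian_lmm(df["y"], df["species"], df["subplot_id"])
        beta_o, vcov_o, su2_o, se2_o, _ = dense_gls_reml(
            df["y"], df["species"], df["subplot_id"]
        )
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-6)
        np.testing.assert_allclose(fit.vcov_fixed, vcov_o, atol=1e-6)
        assert fit.sigma_e2 == pytest.approx(se2_o, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent library cross-check of the REML fixed effects."""
        import statsmodels.formula.api as smf

        df = simulate_gaussian_category(
            {"A": 0.1, "B": 0.3, "C": 0.25}, {"A": 80, "B": 60, "C": 40}, 25,
            sigma_u=0.1, sigma_e=0.25, rng=rng,
        )
        fit = fit_gaussian_lmm(df["y"], df["species"], df["subplot_id"])
        md = smf.mixedlm("y ~ species", df, groups=df["subplot_id"]).fit(reml=True)
        np.testing.assert_allclose(fit.beta, md.fe_params, atol=1e-4)
        assert fit.sigma_u2 == pytest.approx(float(md.cov_re.iloc[0, 0]), abs=1e-4)

    def test_balanced_equal_means_zero_contrast(self):
        """Exactly symmetric data: the species contrast is exactly zero."""
        y = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        species = np.repeat(["A", "B"], 8)
        subplot = np.tile(np.arange(4).repeat(2), 2)
        fit = fit_gaussian_lmm(y, species, subplot)
        con = tukey_shaffer(fit)[0]
        assert con.estimate == pytest.approx(0.0, abs=1e-10)

    def test_empty_level_named_in_error(self):
        with pytest.raises(InferenceError, match="2 species"):
            fit_gaussian_lmm(np.ones(4), ["A"] * 4, [1, 1, 2, 2])

    def test_reml_objective_dominates_grid(self, rng):
        """Optimizer sanity: returned ratio beats a 200-point grid."""
        df = simulate_gaussian_category(
            {"A": 0.2, "B": 0.3}, {"A": 100, "B": 80}, 40, sigma_u=0.08,
            sigma_e=0.2, rng=rng,
        )
        fit = fit_gaussian_lmm(df["y"], df["species"], df["subplot_id"])
        X, levels, gidx, G = _design(df["species"].to_numpy(), df["subplot_id"].to_numpy())
        prof = _REMLProfile(X, df["y"].to_numpy(), gidx, G)
        lam_hat = fit.sigma_u2 / fit.sigma_e2
        obj_hat = (
            prof.neg_reml(np.log(lam_hat)) if lam_hat > 0 else prof.neg_reml_ols()
        )
        grid = np.exp(np.linspace(-12, 8, 200))
        for lam in grid:
            assert obj_hat <= prof.neg_reml(np.log(lam)) + 1e-7


class TestBinomialGLMM:
    def test_sigma_zero_matches_plain_logistic(self, rng):
        import statsmodels.api as sm

        df = simulate_binomial_category(
            {"A": 0.3, "B": 1.0}, {"A": 150, "B": 150}, 40, sigma_u=0.0, rng=rng
        )
        fit = fit_binomial_glmm(
            df["y"], df["species"], df["subplot_id"], fixed_sigma_u2=0.0
        )
        X = np.column_stack([np.ones(len(df)), (df["species"] == "B").astype(float)])
        glm = sm.Logit(df["y"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-4)

    def test_all_alive_species_flags_separation(self, rng):
        df = simulate_binomial_category(
            {"A": 0.5, "B": 0.5}, {"A": 60, "B": 30}, 15, sigma_u=0.2, rng=rng
        )
        df.loc[df["species"] == "B", "y"] = 1.0
        fit = fit_binomial_glmm(df["y"], df["species"], df["subplot_id"])
        assert fit.separation
        assert np.all(np.isfinite(fit.beta))

    def test_non_binary_rejected(self):
        with pytest.raises(InferenceError):
            fit_binomial_glmm([0.5, 1.0], ["A", "B"], [1, 2])

    def test_recovers_truth_at_scale(self, rng):
        """Moderate-size fit recovers the generating log-odds to ~2 SE."""
        truth = {"A": 0.4, "B": 1.2}
        df = simulate_binomial_category(
            truth, {"A": 500, "B": 500}, 100, sigma_u=0.3, rng=rng
        )
        fit = fit_binomial_glmm(df["y"], df["species"], df["subplot_id"])
        lsm = ls_means(fit)
        for sp, est, se in zip(lsm.species, lsm.estimate, lsm.se):
            assert abs(est - truth[sp]) < 3 * se


class TestLSMeans:
    def test_balanced_no_random_effect_equals_group_means(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 2.5, 3.5, 4.5])
        species = np.repeat(["A", "B"], 6)
        subplot = np.tile([1, 2, 3], 4)
        fit = fit_gaussian_lmm(y, species, subplot)
        lsm = ls_means(fit)
        means = {sp: y[np.asarray(species) == sp].mean() for sp in ("A", "B")}
        for sp, est in zip(lsm.species, lsm.estimate):
            assert est == pytest.approx(means[sp], abs=1e-8)

    def test_binomial_zero_logodds_is_half(self, rng):
        df = simulate_binomial_category(
            {"A": 0.0, "B": 0.0}, {"A": 200, "B": 200}, 50, sigma_u=0.0, rng=rng
        )
        fit = fit_binomial_glmm(
            df["y"], df["species"], df["subplot_id"], fixed_sigma_u2=0.0
        )
        lsm = ls_means(fit)
        assert lsm.probability is not None
        # logistic(estimate) is the reported probability
        from scipy.special import expit

        np.testing.assert_allclose(lsm.probability, expit(lsm.estimate))
        assert np.all((lsm.probability > 0) & (lsm.probability < 1))

    def test_unbalanced_gaussian_matches_gls_oracle(self, rng):
        df = simulate_gaussian_category(
            {"A": 0.1, "B": 0.4}, {"A": 50, "B": 12}, 10, sigma_u=0.15,
            sigma_e=0.2, rng=rng,
        )
        fit = fit_gaussian_lmm(df["y"], df["species"], df["subplot_id"])
        lsm = ls_means(fit)
        beta_o, vcov_o, *_ = dense_gls_reml(df["y"], df["species"], df["subplot_id"])
        assert lsm.estimate[0] == pytest.approx(beta_o[0], abs=1e-6)
        assert lsm.estimate[1] == pytest.approx(beta_o[0] + beta_o[1], abs=1e-6)


class TestShaffer:
    @pytest.mark.parametrize("k,expected", [
        (3, [3, 1, 1]),
        (4, [6, 3, 3, 3, 2, 1]),
    ])
    def test_known_multiplier_sequences(self, k, expected):
        assert shaffer_multipliers(k) == expected

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_multipliers_match_partition_enumeration(self, k):
        assert shaffer_multipliers(k) == shaffer_multipliers_bruteforce(k)

    def test_attainable_counts_k4(self):
        assert shaffer_attainable(4) == {6, 3, 2, 1, 0}

    def test_two_species_adjusted_equals_raw(self):
        p = np.array([0.031])
        np.testing.assert_allclose(shaffer_adjust(p, 2), p)

    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=6, max_size=6)
    )
    def test_dominance_shaffer_holm_bonferroni(self, p):
        p = np.asarray(p)
        shaffer = shaffer_adjust(p, 4)
        holm = holm_adjust(p)
        bonf = np.minimum(p * len(p), 1.0)
        assert np.all(shaffer <= holm + 1e-12)
        assert np.all(holm <= bonf + 1e-12)
        assert np.all(shaffer >= p - 1e-12)
        assert np.all((shaffer >= 0) & (shaffer <= 1))
        # monotone in the p-value ordering
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(shaffer[order]) >= -1e-12)


class TestSpeciesInclusion:
    def make(self, mapping):
        rows = []
        for sp, subplots in mapping.items():
            for s in subplots:
                rows.append({"species": sp, "subplot_id": s})
        return pd.DataFrame(rows)

    def test_three_subplots_included(self):
        df = self.make({"A": [1, 2, 3]})
        assert species_inclusion(df) == {"A"}

    def test_many_seedlings_two_subplots_excluded(self):
        df = self.make({"A": [1, 2, 1, 2, 1, 2, 1, 2, 1, 2]})
        assert species_inclusion(df) == set()

    def test_empty_category(self):
        assert species_inclusion(pd.DataFrame(columns=["species", "subplot_id"])) == set()
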