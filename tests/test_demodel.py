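"""Nested-model machinery: weights, duplicate correlation, surrogate
variables, the GLS fit against an OLS oracle, contrasts, and moderation."""

import numpy as np
import pandas as pd
import pytest

from striaseq import demodel


def _design(n, p, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    return pd.DataFrame(X, columns=[f"c{i}" for i in range(p)])


class TestFitOracle:
    def test_unit_weights_zero_rho_match_normal_equations(self):
        """With unit weights, no block correlation, and no shrinkage the
        fit is ordinary least squares to machine precision."""
        rng = np.random.default_rng(0)
        n, p, G = 12, 4, 5
        design = _design(n, p)
        X = design.to_numpy()
        Y = rng.standard_normal((n, G))
        fit = demodel.fit_nested_model(pd.DataFrame(Y, columns=[f"g{i}" for i in range(G)]), design)
        ref = np.linalg.solve(X.T @ X, X.T @ Y).T
        assert np.abs(fit.coef - ref).max() < 1e-10

    def test_moderated_t_reduces_to_ordinary_t_at_zero_prior_df(self):
        rng = np.random.default_rng(1)
        n, p, G = 12, 4, 5
        design = _design(n, p)
        X = design.to_numpy()
        Y = rng.standard_normal((n, G))
        fit = demodel.fit_nested_model(pd.DataFrame(Y, columns=[f"g{i}" for i in range(G)]), design)
        st = demodel.contrast_stats(
            fit, pd.DataFrame({"c1": pd.Series({"c1": 1.0})}), demodel.ebayes(fit, prior_df=0)
        )
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        resid = Y - X @ beta
        s2 = (resid**2).sum(axis=0) / (n - p)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert np.abs(st["t"].to_numpy() - beta[1] / se).max() < 1e-10

    def test_equal_variances_give_infinite_prior_df_and_full_shrinkage(self):
        """When every gene shows the same residual variance there is no
        between-gene spread to estimate: the prior df diverges and all
        posterior variances collapse to one common value."""
        rng = np.random.default_rng(2)
        n, G = 20, 50
        design = _design(n, 3)
        Y = rng.standard_normal((n, G))
        fit = demodel.fit_nested_model(pd.DataFrame(Y), design)
        fit.sigma2 = np.full(G, 0.7)
        mod = demodel.ebayes(fit)
        assert not np.isfinite(mod["df_prior"])
        assert np.ptp(mod["s2_post"]) < 1e-12

    def test_confidence_coverage_of_planted_coefficient(self):
        """A planted coefficient of 1 is covered by the nominal 95% CI at
        least 93% of the time (500 simulations to tame Monte Carlo noise)."""
        cover = 0
        n_sim = 500
        L = pd.DataFrame({"c1": pd.Series({"c1": 1.0})})
        from scipy.stats import t as t_dist

        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            design = _design(12, 3, seed=s)
            X = design.to_numpy()
            Y = (X[:, 1] * 1.0)[:, None] + rng.standard_normal((12, 1))
            fit = demodel.fit_nested_model(pd.DataFrame(Y), design)
            st = demodel.contrast_stats(fit, L, demodel.ebayes(fit, prior_df=0))
            se = st["logFC"].iloc[0] / st["t"].iloc[0]
            half = t_dist.ppf(0.975, fit.df_resid) * se
            cover += abs(st["logFC"].iloc[0] - 1.0) <= half
        assert cover / n_sim >= 0.93

    def test_rank_deficiency_names_aliased_columns(self):
        design = _design(10, 3)
        design["dup"] = design["c1"]
        with pytest.raises(ValueError, match="aliased"):
            demodel.fit_nested_model(pd.DataFrame(np.zeros((10, 2))), design)

    def test_block_correlation_whitening_matches_gls_oracle(self):
        rng = np.random.default_rng(3)
        n = 12
        blocks = np.repeat(np.arange(6), 2)
        design = _design(n, 2, seed=4)
        X = design.to_numpy()
        Y = rng.standard_normal((n, 3))
        rho = 0.4
        fit = demodel.fit_nested_model(pd.DataFrame(Y), design, rho=rho, blocks=blocks)
        C = np.where(blocks[:, None] == blocks[None, :], rho, 0.0)
        np.fill_diagonal(C, 1.0)
        Ci = np.linalg.inv(C)
        ref = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ Y).T
        assert np.abs(fit.coef - ref).max() < 1e-10


class TestPrecisionWeights:
    def test_homoscedastic_input_gives_near_constant_weights(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(24, 2000)).astype(float))
        w, _ = demodel.estimate_precision_weights(counts, _design(24, 2))
        assert np.std(w) / np.mean(w) < 0.2

    def test_noisy_sample_receives_reciprocal_quality_weight(self):
        rng = np.random.default_rng(1)
        n, G = 24, 2000
        Y = rng.standard_normal((n, G))
        Y[0] *= 2.0  # 4x residual variance
        counts = pd.DataFrame(np.round(np.exp(Y + 5)))
        _, swt = demodel.estimate_precision_weights(counts, _design(n, 2))
        assert swt[0] / np.median(swt[1:]) == pytest.approx(0.25, abs=0.075)

    def test_weights_strictly_positive_and_small_gene_fallback(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(20, size=(12, 5)).astype(float))
        with pytest.warns(UserWarning, match="constant"):
            w, _ = demodel.estimate_precision_weights(counts, _design(12, 2))
        assert (w > 0).all()


class TestDuplicateCorrelation:
    def test_recovers_planted_icc(self):
        rng = np.random.default_rng(0)
        blocks = np.repeat(np.arange(30), 2)
        u = rng.standard_normal((30, 1000)) * np.sqrt(0.5)
        e = rng.standard_normal((60, 1000)) * np.sqrt(0.5)
        Y = u[blocks] + e
        rho = demodel.estimate_duplicate_correlation(
            pd.DataFrame(Y), pd.DataFrame(np.ones((60, 1)), columns=["i"]), blocks
        )
        assert rho == pytest.approx(0.5, abs=0.1)

    def test_independent_observations_give_near_zero(self):
        rng = np.random.default_rng(1)
        blocks = np.repeat(np.arange(30), 2)
        Y = rng.standard_normal((60, 1000))
        rho = demodel.estimate_duplicate_correlation(
            pd.DataFrame(Y), pd.DataFrame(np.ones((60, 1)), columns=["i"]), blocks
        )
        assert abs(rho) < 0.05
        assert -1 < rho < 1

    def test_no_repeated_blocks_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no repeated blocks"):
            rho = demodel.estimate_duplicate_correlation(
                pd.DataFrame(np.random.default_rng(0).standard_normal((5, 10))),
                pd.DataFrame(np.ones((5, 1)), columns=["i"]),
                np.arange(5),
            )
        assert rho == 0.0


class TestSurrogateVariables:
    def test_pure_noise_selects_zero_svs_most_of_the_time(self):
        zero = 0
        for s in range(50):
            Y = np.random.default_rng(s).standard_normal((24, 500))
            sv = demodel.estimate_surrogate_variables(
                pd.DataFrame(Y), pd.DataFrame(np.ones((24, 1)), columns=["i"]), seed=s
            )
            zero += sv.shape[1] == 0
        assert zero / 50 >= 0.9

    def test_planted_batch_is_captured_by_first_sv(self):
        rng = np.random.default_rng(7)
        batch = np.repeat([0.0, 1.0], 12)
        Y = rng.standard_normal((24, 500))
        Y[:, :150] += np.outer(batch - 0.5, np.ones(150)) * 2
        sv = demodel.estimate_surrogate_variables(
            pd.DataFrame(Y), pd.DataFrame(np.ones((24, 1)), columns=["i"]), seed=0
        )
        assert sv.shape[1] >= 1
        assert abs(np.corrcoef(sv[:, 0], batch)[0, 1]) >= 0.8

    def test_svs_are_orthogonal_to_the_design(self):
        rng = np.random.default_rng(8)
        design = _design(24, 3, seed=8)
        Y = rng.standard_normal((24, 300)) + np.outer(np.sin(np.arange(24)), np.ones(300))
        sv = demodel.estimate_surrogate_variables(pd.DataFrame(Y), design, n_sv=2, seed=0)
        assert np.abs(design.to_numpy().T @ sv).max() < 1e-8

    def test_requesting_too_many_svs_is_an_error(self):
        with pytest.raises(ValueError, match="residual rank"):
            demodel.estimate_surrogate_variables(
                pd.DataFrame(np.random.default_rng(0).standard_normal((6, 50))),
                _design(6, 2),
                n_sv=5,
            )


class TestContrasts:
    LEVELS = [
        f"{ct}_{dx}_{sex}_{reg}"
        for ct in ("A", "B")
        for dx in ("OUD", "UC")
        for sex in ("F", "M")
        for reg in ("Caudate", "Putamen")
    ]

    @pytest.mark.parametrize("family", ["overall", "within_F", "within_M", "sex_interaction"])
    def test_contrast_weights_sum_to_zero(self, family):
        vec = demodel.build_contrasts(self.LEVELS, family, ["A"])
        assert vec.sum() == pytest.approx(0.0, abs=1e-12)

    def test_overall_contrast_averages_sex_and_region(self):
        vec = demodel.build_contrasts(self.LEVELS, "overall", ["A"])
        oud = [lv for lv in self.LEVELS if lv.startswith("A_OUD")]
        uc = [lv for lv in self.LEVELS if lv.startswith("A_UC")]
        assert np.allclose(vec[oud], 0.25)
        assert np.allclose(vec[uc], -0.25)
        assert np.allclose(vec.drop(oud + uc), 0.0)

    def test_sex_interaction_is_female_minus_male(self):
        inter = demodel.build_contrasts(self.LEVELS, "sex_interaction", ["A"])
        f = demodel.build_contrasts(self.LEVELS, "within_F", ["A"])
        m = demodel.build_contrasts(self.LEVELS, "within_M", ["A"])
        assert np.allclose(inter.to_numpy(), (f - m).to_numpy())

    def test_pooled_scope_averages_member_types(self):
        both = demodel.build_contrasts(self.LEVELS, "overall", ["A", "B"])
        a = demodel.build_contrasts(self.LEVELS, "overall", ["A"])
        b = demodel.build_contrasts(self.LEVELS, "overall", ["B"])
        assert np.allclose(both.to_numpy(), ((a + b) / 2).to_numpy())

    def test_empty_scope_is_an_error(self):
        with pytest.raises(ValueError, match="no levels"):
            demodel.build_contrasts(self.LEVELS, "overall", ["Z"])
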