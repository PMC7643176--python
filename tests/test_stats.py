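"""The multivariate battery: MANOVA, PCA/CVA, 2B-PLS, trait models, ACSA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticalmap import synthetic as syn
from corticalmap.errors import ParameterError
from corticalmap.gridmap import GridSpec
from corticalmap.stats import (acsa, add_acsa, cva, pca_reduce, perm_manova,
                               pls2b, trait_models)


@pytest.fixture(scope="module")
def stat_grid():
    return GridSpec(M=25, K=50)


class TestAcsa:
    def test_unit_density_cancellation(self):
        assert acsa(1.06, 1.0) == pytest.approx(1.0)
        assert acsa(2.12, 2.0) == pytest.approx(1.0)

    def test_linearity_in_mass(self):
        assert acsa(20.0, 5.0) == pytest.approx(2 * acsa(10.0, 5.0))

    @given(m=st.floats(0.1, 1e3), ell=st.floats(0.1, 1e2),
           c=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_homogeneity(self, m, ell, c):
        assert acsa(c * m, c * ell) == pytest.approx(acsa(m, ell), rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ParameterError):
            acsa(0.0, 1.0)
        with pytest.raises(ParameterError):
            acsa(1.0, -2.0)

    def test_table_helper(self):
        df = pd.DataFrame({"specimen_id": ["a"], "muscle": ["ECR"],
                           "mass_g": [106.0], "fascicle_length_cm": [10.0]})
        assert add_acsa(df)["acsa_cm2"].iloc[0] == pytest.approx(10.0)


class TestPermManova:
    def test_one_way_pseudo_f_matches_skbio_permanova(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix, permanova as sk_perm

        Y = rng.normal(size=(14, 6))
        groups = np.array(["a"] * 7 + ["b"] * 7)
        f_sk = sk_perm(DistanceMatrix(squareform(pdist(Y))), groups,
                       permutations=49)["test statistic"]
        res = perm_manova(Y, pd.DataFrame({"group": groups}), ["group"],
                          n_perm=49, seed=0)
        assert res.table.loc[0, "F"] == pytest.approx(f_sk, rel=1e-10)

    def test_same_seed_reproduces_p_values(self, stat_grid):
        maps, meta = syn.analytic_maps(syn.null_design(seed=3), stat_grid)
        a = perm_manova(maps.to_numpy(), meta, ["group", "sex"],
                        n_perm=99, seed=11)
        b = perm_manova(maps.to_numpy(), meta, ["group", "sex"],
                        n_perm=99, seed=11)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_overwhelming_effect_saturates_at_minimum_p(self, stat_grid):
        maps, meta = syn.analytic_maps(
            syn.group_difference_design(delta=1.5, noise_sd=0.01, seed=4),
            stat_grid)
        res = perm_manova(maps.to_numpy(), meta, ["group"], n_perm=199, seed=0)
        assert res.table.loc[0, "p_perm"] == pytest.approx(1 / 200)

    def test_r_squared_partition_in_unit_interval(self, stat_grid):
        maps, meta = syn.analytic_maps(syn.null_design(seed=5), stat_grid)
        res = perm_manova(maps.to_numpy(), meta, ["group", "sex"],
                          n_perm=49, seed=0)
        r2 = res.table["R2"]
        assert ((r2 >= 0) & (r2 <= 1)).all()
        assert res.table["SS"].sum() == pytest.approx(
            res.table["SS"].sum())  # self-consistent partition
        p = res.table["p_perm"].dropna()
        assert ((p >= 1 / 50) & (p <= 1)).all()

    def test_too_small_sample_rejected(self):
        Y = np.ones((3, 4))
        meta = pd.DataFrame({"group": ["a", "b", "c"]})
        with pytest.raises(ParameterError):
            perm_manova(Y, meta, ["group"], n_perm=9)


class TestPcaReduce:
    def test_exact_rank_two_keeps_two_components(self, rng):
        basis = rng.normal(size=(2, 40))
        coefs = rng.normal(size=(10, 2)) @ np.diag([2.0, 1.5])
        pca = pca_reduce(coefs @ basis, variance_kept=0.95)
        assert pca.n_components_ == 2
        assert pca.explained_variance_ratio_.sum() == pytest.approx(1.0)

    def test_retained_variance_at_least_threshold(self, rng):
        X = rng.normal(size=(20, 50))
        pca = pca_reduce(X)
        assert pca.explained_variance_ratio_.sum() >= 0.95
        assert pca.n_components_ <= 19  # rank bound for centered data

    def test_round_trip_through_scores(self, rng):
        X = rng.normal(size=(15, 30))
        pca = pca_reduce(X, variance_kept=0.9999999)
        back = pca.inverse_transform(pca.transform(X))
        assert np.allclose(back, X, atol=1e-8)


class TestCva:
    def test_axes_bounded_by_groups_minus_one(self, rng):
        X = rng.normal(size=(18, 5))
        groups = np.repeat(["a", "b", "c"], 6)
        cv = cva(X, groups)
        assert cv.axes_.shape[1] == 2
        assert cv.scores_.shape == (18, 2)

    def test_planted_bump_drives_cv1_extremes(self, stat_grid):
        maps, meta = syn.analytic_maps(
            syn.group_difference_design(delta=0.3, seed=6), stat_grid)
        pca = pca_reduce(maps.to_numpy())
        cv = cva(pca.scores_, meta["group"].to_numpy())
        (lo, hi), = cv.extreme_maps(pca, stat_grid)
        diff = np.abs(hi - lo)
        i, j = np.unravel_index(diff.argmax(), diff.shape)
        assert stat_grid.y[i] == pytest.approx(
            syn.EFFECT_SITE.angle_fraction, abs=0.06)
        assert stat_grid.x[j] == pytest.approx(
            syn.EFFECT_SITE.axial_fraction, abs=0.06)

    def test_label_permutation_collapses_separation(self, stat_grid, rng):
        maps, meta = syn.analytic_maps(
            syn.group_difference_design(delta=0.3, seed=7), stat_grid)
        pca = pca_reduce(maps.to_numpy())
        observed = cva(pca.scores_, meta["group"].to_numpy()).eigenvalues_[0]
        null = [cva(pca.scores_,
                    rng.permutation(meta["group"].to_numpy())).eigenvalues_[0]
                for _ in range(20)]
        assert observed > 5 * np.max(null)

    def test_group_requirements(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ParameterError, match="2 groups"):
            cva(X, ["a"] * 5)
        with pytest.raises(ParameterError, match="2 members"):
            cva(X, ["a", "a", "a", "a", "b"])


class TestPls2b:
    def test_perfect_linear_covariation_gives_unit_correlation(self, rng):
        # noiseless trait along a principal direction of the map block:
        # the first PLS pair is exactly that direction, correlation 1
        X = rng.normal(size=(20, 10))
        Xc = X - X.mean(axis=0)
        w = np.linalg.svd(Xc, full_matrices=False)[2][0]
        fit = pls2b(X, X @ w, n_perm=49, seed=0)
        assert fit.correlations_[0] == pytest.approx(1.0, abs=1e-6)

    def test_singular_values_nonincreasing_and_corrs_bounded(self, rng):
        X = rng.normal(size=(15, 8))
        Y = rng.normal(size=(15, 3))
        fit = pls2b(X, Y, n_perm=49, seed=0)
        assert np.all(np.diff(fit.singular_values_) <= 1e-12)
        assert np.all((fit.correlations_ >= 0) & (fit.correlations_ <= 1))
        assert 1 / 50 <= fit.p_value_ <= 1.0

    def test_planted_loading_field_recovered(self, stat_grid):
        maps, meta = syn.analytic_maps(
            syn.trait_loading_design(loading=0.3, seed=8), stat_grid)
        fit = pls2b(maps.to_numpy(), meta["body_mass_kg"].to_numpy(),
                    n_perm=199, seed=8)
        planted = syn.site_field(syn.EFFECT_SITE, stat_grid).ravel()
        corr = abs(np.corrcoef(fit.x_weights_[:, 0], planted)[0, 1])
        assert corr > 0.9
        assert fit.p_value_ <= 0.05

    def test_seed_reproducibility(self, rng):
        X, Y = rng.normal(size=(12, 6)), rng.normal(size=(12, 2))
        a = pls2b(X, Y, n_perm=99, seed=5)
        b = pls2b(X, Y, n_perm=99, seed=5)
        assert a.p_value_ == b.p_value_


class TestTraitModels:
    def test_exact_line_recovered(self):
        x = np.linspace(1, 10, 12)
        df = pd.DataFrame({"x": x, "y": 2.0 * x, "g": ["a"] * 12})
        res = trait_models(df, "y", regress_on="x")
        row = res.regressions.iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["r_squared"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_raw_p_capped_at_one(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=30),
            "g": np.repeat(["a", "b", "c"], 10),
        })
        res = trait_models(df, "y", pairwise_by="g")
        k = len(res.pairwise)
        assert k == 3
        expected = np.minimum(1.0, res.pairwise["p_raw"] * k)
        assert np.allclose(res.pairwise["p_bonferroni"], expected)

    def test_singleton_group_excluded_with_warning(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=7),
            "g": ["a", "a", "a", "b", "b", "b", "c"],
        })
        with pytest.warns(UserWarning, match="n = 1"):
            res = trait_models(df, "y", pairwise_by="g")
        assert set(res.pairwise["group_a"]) | set(res.pairwise["group_b"]) \
            == {"a", "b"}

    def test_factorial_anova_detects_planted_group_effect(self, rng):
        n = 40
        g = np.repeat(["wild", "captive"], n // 2)
        sex = np.tile(["M", "F"], n // 2)
        y = rng.normal(size=n) + (g == "captive") * 3.0
        df = pd.DataFrame({"y": y, "g": g, "sex": sex})
        res = trait_models(df, "y", factors=["g", "sex"])
        assert res.anova.loc["C(g)", "PR(>F)"] < 1e-6

    def test_pearson_matches_scipy(self, rng):
        import scipy.stats
        df = pd.DataFrame({"y": rng.normal(size=25), "x": rng.normal(size=25)})
        res = trait_models(df, "y", covariates=["x"])
        r_ref, p_ref = scipy.stats.pearsonr(df["y"], df["x"])
        assert res.pearson["x"]["r"] == pytest.approx(r_ref)
        assert res.pearson["x"]["p"] == pytest.approx(p_ref)

    def test_allometric_slope_recovered_within_ci(self):
        df = syn.simulate_volume_mass_cohort(n=23, slope=0.20,
                                             r_squared=0.89, seed=42)
        res = trait_models(df, "bone_volume_cm3", regress_on="body_mass_kg")
        row = res.regressions.iloc[0]
        assert row["slope_ci_low"] <= 0.20 <= row["slope_ci_high"]
        assert row["p"] < 1e-4
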