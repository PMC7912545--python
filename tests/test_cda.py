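"""Canonical discriminant analysis: screens, eigen-solution, classification."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

import pedstruct as ps
from pedstruct.cda import _scatter


def gaussian_groups(rng, n_per=60, p=4, separation=2.0, g=3):
    """Well-defined multivariate normal groups with shifted means."""
    blocks, labels = [], []
    for k in range(g):
        mu = np.zeros(p)
        mu[k % p] = separation * k
        blocks.append(rng.normal(size=(n_per, p)) + mu)
        labels += [f"G{k}"] * n_per
    X = pd.DataFrame(np.vstack(blocks), columns=[f"x{j}" for j in range(p)])
    return X, pd.Series(labels, index=X.index)


class TestVifScreen:
    def test_orthogonal_columns_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]}, dtype=float)
        cols, table, removed = ps.vif_screen(X, threshold=4.0)
        assert removed == []
        assert table["a"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_removed_with_infinite_vif(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        cols, table, removed = ps.vif_screen(X, threshold=4.0)
        assert len(removed) == 1 and removed[0] in ("a", "b")
        assert "c" in cols

    def test_near_linear_combination_has_largest_vif(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=200), rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2 + rng.normal(scale=1e-3, size=200)})
        _, _, removed = ps.vif_screen(X, threshold=4.0)
        assert removed[0] == "x3"


class TestPcaScreen:
    def test_uncorrelated_columns_all_retained(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        retained, flagged, _ = ps.pca_screen(X, loading_threshold=0.5)
        assert flagged == []
        assert retained == list("abcd")

    def test_zero_threshold_is_vacuous(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        retained, flagged, _ = ps.pca_screen(X, loading_threshold=0.0)
        assert flagged == []

    def test_noise_column_has_lowest_max_loading(self):
        rng = np.random.default_rng(4)
        factor = rng.normal(size=400)
        X = pd.DataFrame(
            {
                "f1a": factor + 0.1 * rng.normal(size=400),
                "f1b": factor + 0.1 * rng.normal(size=400),
                "f1c": -factor + 0.1 * rng.normal(size=400),
                "noise": rng.normal(size=400),
            }
        )
        _, _, loadings = ps.pca_screen(X)
        max_abs = loadings.abs().max(axis=1)
        assert max_abs.idxmin() == "noise"


class TestStepwise:
    def test_perfect_separator_enters_first(self):
        rng = np.random.default_rng(5)
        n = 90
        groups = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        X = pd.DataFrame(
            {
                "signal": np.repeat([0.0, 5.0, 10.0], 30) + 0.1 * rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        table = ps.stepwise_select(X, groups)
        assert table["variable"].iloc[0] == "signal"

    def test_infinite_threshold_raises(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        groups = pd.Series(["A"] * 20 + ["B"] * 20)
        with pytest.raises(ValueError, match="F-to-enter"):
            ps.stepwise_select(X, groups, f_to_enter=np.inf)

    def test_informative_variables_enter_before_noise(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_per, g = 40, 3
            labels = pd.Series(np.repeat([f"G{k}" for k in range(g)], n_per))
            cols = {}
            for j in range(3):  # informative: distinct group means
                shift = rng.permutation([0.0, 1.5, 3.0])
                cols[f"inf{j}"] = np.repeat(shift, n_per) + rng.normal(size=n_per * g)
            for j in range(3):
                cols[f"noise{j}"] = rng.normal(size=n_per * g)
            X = pd.DataFrame(cols)
            table = ps.stepwise_select(X, labels, f_to_enter=0.0)
            entered = list(table["variable"])
            inf_ranks = [entered.index(c) for c in ("inf0", "inf1", "inf2")]
            noise_ranks = [entered.index(c) for c in entered if c.startswith("noise")]
            wins += max(inf_ranks) < (min(noise_ranks) if noise_ranks else len(entered))
        assert wins >= 18


class TestFitCda:
    def test_eigen_identities(self):
        rng = np.random.default_rng(7)
        X, groups = gaussian_groups(rng)
        model = ps.fit_cda(X, groups)
        lam = model.eigenvalues
        assert np.allclose(model.canonical_correlations**2, lam / (1 + lam), atol=1e-12)
        assert model.wilks_lambda == pytest.approx(float(np.prod(1 / (1 + lam))), abs=1e-12)
        assert model.variance_explained.sum() == pytest.approx(1.0)

    def test_matches_explicit_generalized_eigen_oracle(self):
        rng = np.random.default_rng(8)
        X, groups = gaussian_groups(rng, n_per=50, p=5)
        model = ps.fit_cda(X, groups)
        W, B, _, _ = _scatter(X.to_numpy(), np.asarray(groups))
        vals = np.linalg.eigvals(np.linalg.solve(W, B))
        vals = np.sort(np.real(vals))[::-1][: len(model.eigenvalues)]
        assert np.max(np.abs(vals - model.eigenvalues)) < 1e-8

    def test_scores_have_unit_pooled_within_variance(self):
        rng = np.random.default_rng(9)
        X, groups = gaussian_groups(rng)
        model = ps.fit_cda(X, groups)
        scores = (X.to_numpy() - model.grand_mean) @ model.raw_coefficients.to_numpy()
        g = np.asarray(groups)
        n, k = len(X), len(model.groups)
        pooled = sum(
            ((scores[g == lab] - scores[g == lab].mean(axis=0)) ** 2).sum(axis=0)
            for lab in model.groups
        ) / (n - k)
        assert np.allclose(pooled, 1.0, atol=1e-10)

    def test_identical_groups_give_near_zero_eigenvalues(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        groups = pd.Series(["A", "B"] * 100)
        model = ps.fit_cda(X, groups)
        assert model.eigenvalues[0] < 0.05
        assert not model.meaningful.any()

    def test_collinear_column_reported_by_name(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=60)})
        groups = pd.Series(["A"] * 30 + ["B"] * 30)
        with pytest.raises(ValueError, match="singular"):
            ps.fit_cda(X, groups)

    def test_wilks_chi_square_df_sequence(self):
        rng = np.random.default_rng(12)
        X, groups = gaussian_groups(rng, p=6, g=3)
        model = ps.fit_cda(X, groups)
        assert list(model.wilks["df"]) == [12, 5]  # p(g-1), then (p-1)(g-2)

    def test_pillai_equals_sum_of_squared_canonical_correlations(self):
        rng = np.random.default_rng(13)
        X, groups = gaussian_groups(rng)
        model = ps.fit_cda(X, groups)
        assert model.pillai["trace"] == pytest.approx(
            float((model.canonical_correlations**2).sum())
        )


class TestMahalanobis:
    def test_equals_canonical_space_distance(self):
        rng = np.random.default_rng(14)
        X, groups = gaussian_groups(rng, p=4, g=3)
        model = ps.fit_cda(X, groups)
        D2 = ps.mahalanobis_between(model)
        cent = model.centroids.to_numpy()
        for i, a in enumerate(model.groups):
            for j, b in enumerate(model.groups):
                expect = float(((cent[i] - cent[j]) ** 2).sum())
                assert D2.loc[a, b] == pytest.approx(expect, rel=1e-8, abs=1e-10)

    def test_zero_diagonal_symmetric(self):
        rng = np.random.default_rng(15)
        X, groups = gaussian_groups(rng)
        D2 = ps.mahalanobis_between(ps.fit_cda(X, groups))
        assert np.allclose(np.diag(D2.to_numpy()), 0.0)
        assert np.allclose(D2.to_numpy(), D2.to_numpy().T)


class TestClassification:
    def test_press_q_closed_forms(self):
        # the three-breed studbook worked example, and an all-correct case
        assert round(ps.press_q(207_100, 197_026, 3), 2) == 355_961.14
        assert ps.press_q(100, 100, 2) == pytest.approx(100.0)

    def test_chi_square_reference_value(self):
        from pedstruct.cda import CHI2_CRIT_1DF_01

        assert round(CHI2_CRIT_1DF_01, 2) == 6.63

    def test_well_separated_groups_classify_almost_perfectly(self):
        rng = np.random.default_rng(16)
        X, groups = gaussian_groups(rng, separation=6.0)
        rep = ps.classify_loocv(X, groups)
        assert rep.loocv_hit_ratio > 0.95
        assert rep.press_q_significant

    def test_downdate_agrees_with_exact_refit(self):
        rng = np.random.default_rng(17)
        X, groups = gaussian_groups(rng, n_per=25, separation=1.5)
        down = ps.classify_loocv(X, groups, method="downdate")
        refit = ps.classify_loocv(X, groups, method="refit")
        assert down.loocv_confusion.equals(refit.loocv_confusion)

    def test_loocv_not_better_than_resubstitution_on_average(self):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, groups = gaussian_groups(rng, n_per=30, separation=1.0)
            rep = ps.classify_loocv(X, groups)
            diffs.append(rep.hit_ratio - rep.loocv_hit_ratio)
        assert np.mean(diffs) >= 0.0

    def test_classification_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(18)
        X, groups = gaussian_groups(rng)
        rep1 = ps.classify_loocv(X, groups)
        X2 = X.copy()
        X2["x0"] = 1000.0 * X2["x0"] - 7.0
        rep2 = ps.classify_loocv(X2, groups)
        assert rep1.loocv_confusion.equals(rep2.loocv_confusion)

    def test_matches_sklearn_lda_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(19)
        X, groups = gaussian_groups(rng, separation=1.5)
        model = ps.fit_cda(X, groups)
        ours = ps.classify(model, X)
        lda = LinearDiscriminantAnalysis(solver="svd").fit(X.to_numpy(), np.asarray(groups))
        theirs = lda.predict(X.to_numpy())
        assert (ours == theirs).mean() > 0.99


class TestTerritorial:
    def test_centroids_equal_group_score_means(self):
        rng = np.random.default_rng(20)
        X, groups = gaussian_groups(rng)
        model = ps.fit_cda(X, groups)
        coords = ps.territorial_coordinates(model, X, groups)
        pts = coords[~coords["is_centroid"]]
        cents = coords[coords["is_centroid"]]
        for g in model.groups:
            got = cents[cents["group"] == g][["F1", "F2"]].to_numpy()[0]
            expect = pts[pts["group"] == g][["F1", "F2"]].to_numpy().mean(axis=0)
            assert np.allclose(got, expect, atol=1e-10)

    def test_sizeweighted_grand_mean_of_scores_is_zero(self):
        rng = np.random.default_rng(21)
        X, groups = gaussian_groups(rng)
        model = ps.fit_cda(X, groups)
        coords = ps.territorial_coordinates(model, X, groups)
        pts = coords[~coords["is_centroid"]][["F1", "F2"]].to_numpy()
        assert np.allclose(pts.mean(axis=0), 0.0, atol=1e-10)


class TestFeatureAssembly:
    def test_columns_and_group_alignment(self, composite_small):
        ped, _ = composite_small
        X, groups = ps.assemble_features(ped)
        assert {"F_pct", "AR_pct", "alpha", "GCI", "max_generations",
                "complete_generations", "equivalent_generations", "n_offspring"} == set(X.columns)
        assert len(X) == len(groups) == int(ped.focal.sum())
        assert not X.isna().any().any()
        assert set(groups) == {"A", "B", "AB"}
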