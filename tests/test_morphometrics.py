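"""Shape analysis oracles: centroid size, GPA, allometry, PCA, UPGMA,
discriminant analysis and group tests, each against an independent
closed-form, brute-force or simulation oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphdiverge as md
from morphdiverge.morphometrics import AllometryResult, _scatter_matrices
from morphdiverge.types import HEAD_LANDMARKS, N_LANDMARKS, DegenerateConfigurationError

SQUARE = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])


def _random_config(rng, k=24):
    return rng.normal(size=(k, 2))


def _similarity(coords, rng):
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return coords @ rot.T * rng.uniform(0.5, 3.0) + rng.uniform(-10, 10, 2)


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        assert md.centroid_size(SQUARE) == pytest.approx(np.sqrt(2.0))

    def test_translation_invariance(self, rng):
        c = _random_config(rng)
        assert md.centroid_size(c + np.array([7.0, -3.0])) == pytest.approx(
            md.centroid_size(c), rel=1e-12
        )

    def test_scales_linearly(self, rng):
        c = _random_config(rng)
        assert md.centroid_size(3.5 * c) == pytest.approx(
            3.5 * md.centroid_size(c), rel=1e-12
        )

    def test_brute_force_formula(self, rng):
        c = _random_config(rng)
        centroid = c.mean(axis=0)
        brute = np.sqrt(sum((x - centroid[0]) ** 2 + (y - centroid[1]) ** 2
                            for x, y in c))
        assert abs(md.centroid_size(c) - brute) < 1e-12

    def test_degenerate_configuration_raises(self):
        with pytest.raises(DegenerateConfigurationError):
            md.centroid_size(np.ones((24, 2)))


class TestGPA:
    def test_identical_copies_have_zero_procrustes_distance(self, rng):
        c = _random_config(rng)
        sup = md.gpa([c, c.copy(), c.copy()])
        d = np.linalg.norm(sup.aligned[0] - sup.aligned[1])
        assert d < 1e-12
        # consensus is the common shape at unit size
        assert md.centroid_size(sup.consensus) == pytest.approx(1.0, abs=1e-9)

    def test_similarity_transformed_copy_aligns_exactly(self, rng):
        c = _random_config(rng)
        sup = md.gpa([c, _similarity(c, rng)])
        assert np.abs(sup.aligned[0] - sup.aligned[1]).max() < 1e-8

    def test_output_invariant_to_input_similarity_transforms(self, rng):
        configs = [_random_config(rng) for _ in range(5)]
        sup1 = md.gpa(configs)
        sup2 = md.gpa([_similarity(c, rng) for c in configs])
        assert np.abs(sup1.aligned - sup2.aligned).max() < 1e-8

    def test_two_shape_closed_form_oracle(self, rng):
        """GPA of two shapes equals the ordinary Procrustes solution."""
        a, b = _random_config(rng, 3), _random_config(rng, 3)

        def unit(x):
            x = x - x.mean(axis=0)
            return x / np.linalg.norm(x)

        au, bu = unit(a), unit(b)
        m = au.T @ bu
        s = np.linalg.svd(m, compute_uv=False)
        trace = s[0] + np.sign(np.linalg.det(m)) * s[1]  # reflections barred
        d_closed = np.sqrt(max(2.0 - 2.0 * trace, 0.0))
        sup = md.gpa([a, b])
        d_gpa = np.linalg.norm(sup.aligned[0] - sup.aligned[1])
        assert abs(d_gpa - d_closed) < 1e-8

    def test_aligned_configurations_centered(self, superimposed):
        centroids = superimposed.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        assert md.centroid_size(superimposed.consensus) == pytest.approx(1, abs=1e-9)

    def test_degenerate_specimen_named(self, rng):
        good = _random_config(rng)
        with pytest.raises(DegenerateConfigurationError, match="specimen_2"):
            md.gpa([good, np.zeros((24, 2))])


class TestAllometry:
    def test_residuals_orthogonal_to_size(self, superimposed):
        res = md.allometry_residuals(superimposed)
        s = res.size - res.size.mean()
        corr = s @ res.residuals
        assert np.abs(corr).max() < 1e-8

    def test_null_allometry_explains_nothing(self, rng):
        shapes = [_random_config(rng) * rng.uniform(0.5, 2.0) for _ in range(200)]
        sup = md.gpa(shapes)
        res = md.allometry_residuals(sup)
        assert res.pct_variance_explained < 2.0

    def test_known_allometry_vector_recovered(self, templates, rng):
        from dataclasses import replace

        plank = templates[0]
        vec = np.zeros((N_LANDMARKS, 2))
        vec[[3, 7, 15], 1] = (0.05, -0.04, 0.03)
        tpl = replace(plank, allometry_vector=vec, shape_sd=0.001)
        sets, _ = md.simulate_landmarks((tpl, tpl), (250, 250), seed=77)
        sup = md.gpa(sets)
        res = md.allometry_residuals(sup, size_transform="log")
        # express the planted vector in the superimposition frame: centered
        # (translation is removed by GPA) and rotated template -> consensus
        from scipy.linalg import orthogonal_procrustes

        rot, _ = orthogonal_procrustes(tpl.mean_shape, sup.consensus)
        truth = ((vec - vec.mean(axis=0)) @ rot).ravel()
        corr = np.corrcoef(res.slope, truth)[0, 1]
        assert corr > 0.99

    def test_zero_size_variance_rejected(self, rng):
        c = _random_config(rng)
        sup = md.gpa([_similarity(c, rng) for _ in range(5)])
        sup.centroid_sizes[:] = 2.0
        with pytest.raises(ValueError, match="variance"):
            md.allometry_residuals(sup)


class TestShapePCA:
    def test_rank_one_data_is_single_component(self, rng):
        direction = rng.normal(size=6)
        x = np.outer(rng.normal(size=30), direction)
        pca = md.shape_pca(x)
        assert pca.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_uncorrelated(self, rng):
        x = rng.normal(size=(40, 6))
        pca = md.shape_pca(x)
        cov = np.cov(pca.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10

    def test_eigenvalues_match_spectral_oracle(self, rng):
        x = rng.normal(size=(10, 6))
        pca = md.shape_pca(x)
        oracle = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, oracle[: len(pca.eigenvalues)],
                                   atol=1e-10)

    def test_variance_proportions_monotone(self, superimposed):
        res = md.allometry_residuals(superimposed)
        pca = md.shape_pca(res.residuals)
        assert np.all(np.diff(pca.variance_explained) <= 1e-12)
        assert pca.variance_explained.sum() <= 1 + 1e-9


class TestFeatureMatrix:
    def test_default_is_nine_columns(self, study, superimposed):
        res = md.allometry_residuals(superimposed)
        pca = md.shape_pca(res.residuals)
        x, names = md.feature_matrix(study.traits, pca, n_pcs=2)
        assert x.shape == (154, 9)
        assert names[-2:] == ["PC1", "PC2"]

    def test_standardization(self, study, superimposed):
        res = md.allometry_residuals(superimposed)
        pca = md.shape_pca(res.residuals)
        x, _ = md.feature_matrix(study.traits, pca, n_pcs=2, standardize=True)
        np.testing.assert_allclose(x.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(x.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_zero_pcs_gives_traits_only(self, study):
        x, names = md.feature_matrix(study.traits, None, n_pcs=0)
        assert x.shape[1] == 7 and "PC1" not in names

    def test_missing_trait_column_raises(self, study, superimposed):
        res = md.allometry_residuals(superimposed)
        pca = md.shape_pca(res.residuals)
        with pytest.raises(KeyError, match="JawD"):
            md.feature_matrix(study.traits.drop(columns=["JawD"]), pca)


class TestUPGMA:
    def test_hand_worked_four_leaf_tree(self):
        # 1-D points 0, 2, 10, 12: d(A,B)=2, d(C,D)=2, average-linkage
        # cross distance mean(10, 12, 8, 10) = 10
        x = np.array([[0.0], [2.0], [10.0], [12.0]])
        res = md.upgma(x)
        np.testing.assert_allclose(sorted(res.heights), [2.0, 2.0, 10.0])
        assert set(map(tuple, [sorted(res.labels[:2]), sorted(res.labels[2:])])) == {
            (1, 1), (2, 2)
        }

    def test_well_separated_blobs_recovered(self, rng):
        a = rng.normal(0.0, 1.0, size=(40, 3))
        b = rng.normal(10.0, 1.0, size=(40, 3))
        res = md.upgma(np.vstack([a, b]))
        truth = np.repeat([0, 1], 40)
        assert md.cluster_agreement(res.labels, truth) == 1.0

    def test_duplicates_merge_first_at_zero_height(self, rng):
        x = rng.normal(size=(5, 2))
        res = md.upgma(np.vstack([x, x[:1]]))
        assert res.heights[0] == 0.0

    def test_ultrametric_heights_nondecreasing(self, rng):
        x = rng.normal(size=(30, 4))
        res = md.upgma(x)
        assert np.all(np.diff(res.heights) >= -1e-12)

    def test_order_invariance_up_to_relabeling(self, rng):
        x = rng.normal(size=(20, 3))
        perm = rng.permutation(20)
        r1 = md.upgma(x)
        r2 = md.upgma(x[perm])
        assert md.cluster_agreement(r1.labels[perm], r2.labels) == 1.0


class TestLDA:
    def test_no_separation_gives_lambda_one(self, rng):
        x = rng.normal(size=(60, 3))
        labels = np.repeat(["a", "b"], 30)
        x[labels == "b"] -= x[labels == "b"].mean(axis=0) - x[labels == "a"].mean(axis=0)
        res = md.lda_two_group(x, labels)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-9)

    def test_univariate_lambda_matches_t_statistic(self, rng):
        """1-D Wilks' lambda equals 1 / (1 + t^2 / (n - 2))."""
        a, b = rng.normal(0, 1, 17), rng.normal(0.8, 1, 13)
        x = np.concatenate([a, b])[:, None]
        labels = np.array(["a"] * 17 + ["b"] * 13)
        res = md.lda_two_group(x, labels)
        t, _ = stats.ttest_ind(a, b)
        oracle = 1.0 / (1.0 + t**2 / (len(x) - 2))
        assert abs(res.wilks_lambda - oracle) < 1e-10

    def test_separated_blobs_classified_perfectly(self, rng):
        a = rng.normal(0, 1, size=(25, 4))
        b = rng.normal(10, 1, size=(25, 4))
        labels = np.repeat(["a", "b"], 25)
        res = md.lda_two_group(np.vstack([a, b]), labels)
        assert res.jackknife_pct["a"] == 100.0 and res.jackknife_pct["b"] == 100.0
        assert res.confusion[0, 1] == 0 and res.confusion[1, 0] == 0

    def test_lambda_decreases_with_separation(self, rng):
        noise = rng.normal(size=(80, 3))
        labels = np.repeat(["a", "b"], 40)
        lams = []
        for sep in (0.0, 0.5, 1.0, 2.0, 4.0):
            x = noise.copy()
            x[40:, 0] += sep
            lams.append(md.lda_two_group(x, labels).wilks_lambda)
        assert all(l2 < l1 for l1, l2 in zip(lams, lams[1:]))
        assert all(0 < l <= 1 for l in lams)

    def test_matches_sklearn_on_separated_data(self, rng):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        a = rng.normal(0, 1, size=(30, 3))
        b = rng.normal(3, 1, size=(30, 3))
        x = np.vstack([a, b])
        labels = np.repeat(["a", "b"], 30)
        ours = md.lda_two_group(x, labels)
        ref = sklearn_lda().fit(x, labels)
        # discriminant directions proportional
        cos = abs(ref.coef_[0] @ ours.axis) / np.linalg.norm(ref.coef_[0])
        assert cos > 1 - 1e-8

    def test_singular_within_matrix_needs_ridge(self):
        x = np.zeros((8, 3))
        x[4:, 0] = 1.0  # zero within-group variance
        labels = np.repeat(["a", "b"], 4)
        with pytest.raises(np.linalg.LinAlgError):
            md.lda_two_group(x, labels)
        res = md.lda_two_group(x, labels, ridge=1e-6)
        assert res.ridge_used


class TestMANOVA:
    def test_wilks_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        x = rng.normal(size=(40, 3))
        labels = np.repeat(["a", "b"], 20)
        x[20:] += 0.8
        ours = md.manova_and_posthoc(x, labels)
        sm_res = MANOVA(x, pd.get_dummies(labels, drop_first=False).to_numpy(float))
        tbl = sm_res.mv_test(
            hypotheses=[("grp", np.array([[1.0, -1.0]]), None)]
        ).results["grp"]["stat"]
        assert ours["wilks_lambda"] == pytest.approx(
            float(tbl.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert ours["F"] == pytest.approx(
            float(tbl.loc["Wilks' lambda", "F Value"]), rel=1e-6
        )

    def test_null_type_i_error_calibrated(self):
        """Per-variable univariate tests reject ~5% under the null."""
        rng = np.random.default_rng(202)
        labels = np.repeat(["a", "b"], 12)
        rejections = 0
        trials = 0
        for _ in range(1000):
            x = rng.normal(size=(24, 3))
            res = md.manova_and_posthoc(x, labels)
            for row in res["per_variable"]:
                trials += 1
                rejections += row["p"] < 0.05
        assert 0.03 < rejections / trials < 0.07

    def test_published_trait_contrasts_all_significant(self, study):
        """At the study sample sizes the seven linear traits separate the
        morphs decisively, as in the source population."""
        x, names = md.feature_matrix(study.traits, None, n_pcs=0, standardize=False)
        res = md.manova_and_posthoc(x, study.labels, names)
        assert res["p"] < 0.001
        for row in res["per_variable"]:
            assert row["p"] < 0.001, row

    def test_constant_variable_flagged_not_crashing(self, rng):
        x = rng.normal(size=(20, 2))
        x[:, 1] = 3.14
        res = md.manova_and_posthoc(x, np.repeat(["a", "b"], 10))
        assert res["per_variable"][1]["undefined"]


class TestANCOVA:
    def test_null_covariate_p_uniform(self):
        rng = np.random.default_rng(303)
        pvals = []
        group = np.repeat(["a", "b"], 15)
        for _ in range(200):
            trait = rng.normal(size=30) + (group == "b") * 0.5
            cov = rng.random(30) < 0.3
            pvals.append(md.ancova_covariate(trait, group, cov)["p_cov"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_covariate_dominated_trait(self, rng):
        group = np.repeat(["a", "b"], 20)
        cov = rng.random(40) < 0.5
        trait = 2.0 * cov + rng.normal(0, 1e-3, 40)
        res = md.ancova_covariate(trait, group, cov)
        assert res["F_cov"] > 1000 and res["p_group"] > 0.05

    def test_all_flags_identical_drops_covariate(self, rng):
        group = np.repeat(["a", "b"], 10)
        res = md.ancova_covariate(rng.normal(size=20), group, np.zeros(20))
        assert res["covariate_dropped"] and np.isnan(res["F_cov"])

    def test_zero_variance_trait_flagged(self):
        group = np.repeat(["a", "b"], 10)
        res = md.ancova_covariate(np.ones(20), group, np.zeros(20))
        assert res["undefined"]


class TestMeanShapeByGroup:
    def test_single_group_equals_consensus_direction(self, superimposed, study):
        out = md.mean_shape_by_group(superimposed, np.repeat("all", 154))
        mean_all = out["means"]["all"]
        # group mean of aligned shapes ~ consensus up to iteration tolerance
        diff = mean_all / np.linalg.norm(mean_all) - superimposed.consensus
        assert np.abs(diff).max() < 1e-6

    def test_planted_difference_concentrated_in_head(self, superimposed, study):
        out = md.mean_shape_by_group(superimposed, study.labels)
        delta = out["difference"]
        body = np.setdiff1d(np.arange(N_LANDMARKS), HEAD_LANDMARKS)
        head_norm = np.linalg.norm(delta[list(HEAD_LANDMARKS)])
        body_norm = np.linalg.norm(delta[body])
        assert head_norm > 2.5 * body_norm

    def test_permuted_labels_give_similar_means(self, superimposed, study, rng):
        perm = rng.permutation(study.labels)
        out = md.mean_shape_by_group(superimposed, perm)
        a, b = (out["means"][g] for g in ("planktivorous", "benthivorous"))
        planted = md.mean_shape_by_group(superimposed, study.labels)["difference"]
        # permuted group means differ only by exchangeable sampling noise,
        # well below the planted between-morph displacement
        assert np.linalg.norm(a - b) < 0.6 * np.linalg.norm(planted)

    def test_empty_group_raises(self, superimposed):
        with pytest.raises(ValueError):
            md.mean_shape_by_group(superimposed, np.array([]))
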