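"""Shape model: correspondence, alignment, PDM, group tests, LDA."""

import numpy as np
import pytest
from scipy import stats as sps

from neocardio.contours import ContourSet, generate_contour
from neocardio.shape import (
    PointDistributionModel,
    ProcrustesAligner,
    ShapeLDA,
    centroid_size,
    generalized_procrustes,
    kabsch_rotation_2d,
    loo_auc,
    mann_whitney_auc,
    per_mode_group_test,
    resample_contour,
    select_mode_subset,
    train_lda,
)


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def contour_population(n, rng, globularity=0.0, g_sd=0.25, size=1.4,
                       size_cv=0.08, noise=0.01, n_points=40):
    shapes = []
    for _ in range(n):
        g = float(np.clip(rng.normal(globularity, g_sd), -1, 1))
        s = max(size * (1 + rng.normal(0, size_cv)), 0.2)
        endo, _ = generate_contour(g, s, n_points=n_points, noise_sd=noise,
                                   seed=np.random.default_rng(
                                       rng.integers(2 ** 31)))
        shapes.append(endo.points)
    return np.stack(shapes)


class TestResampleContour:
    def test_uniform_contour_is_fixed_point(self):
        t = np.linspace(0, np.pi, 50)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        # equalise spacing first, then resampling must be the identity
        c0 = ContourSet(pts, "endocardial")
        c1 = resample_contour(c0, 50)
        c2 = resample_contour(c1, 50)
        np.testing.assert_allclose(c1.points, c2.points, atol=1e-9)

    def test_arc_length_preserved_on_smooth_family(self):
        endo, _ = generate_contour(0.2, 1.5, n_points=3000, noise_sd=0.0)
        dense_len = endo.arc_length()  # near-continuum reference
        coarse = resample_contour(endo, 50)
        assert coarse.arc_length() == pytest.approx(dense_len, rel=0.005)

    def test_doubling_points_halves_spacing(self):
        endo, _ = generate_contour(0.0, 1.4, n_points=200, noise_sd=0.0)
        def max_gap(c):
            return np.max(np.linalg.norm(np.diff(c.points, axis=0), axis=1))
        g50 = max_gap(resample_contour(endo, 50))
        g100 = max_gap(resample_contour(endo, 100))
        assert g100 == pytest.approx(g50 / 2, rel=0.05)

    def test_landmarks_at_corners_and_apex(self):
        endo, _ = generate_contour(0.3, 1.5, n_points=90, noise_sd=0.0)
        r = resample_contour(endo, 51)
        assert r.landmarks["corner_a"] == 0
        assert r.landmarks["corner_b"] == 50
        apex_old = endo.points[endo.landmarks["apex"]]
        assert np.linalg.norm(r.points[r.landmarks["apex"]] - apex_old) < 0.1


class TestProcrustes:
    def test_identical_shapes_under_rotation_align_exactly(self, rng):
        base = contour_population(1, rng)[0]
        shapes = np.stack([base, (base - base.mean(0)) @ rot(np.pi / 6).T
                           + np.array([2.0, -1.0])])
        aligned = generalized_procrustes(shapes)
        rmsd = np.sqrt(np.mean((aligned.shapes[0] - aligned.shapes[1]) ** 2))
        assert rmsd < 1e-8

    def test_rotations_are_proper(self, rng):
        shapes = contour_population(8, rng, noise=0.03)
        aligned = generalized_procrustes(shapes)
        for r in aligned.rotations:
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_per_shape_rotation_is_kabsch_optimal(self, rng):
        # at convergence no further rotation towards the mean helps
        shapes = contour_population(10, rng, noise=0.02)
        aligned = generalized_procrustes(shapes)
        mean = aligned.mean_shape
        for s in aligned.shapes:
            r = kabsch_rotation_2d(s, mean)
            np.testing.assert_allclose(r, np.eye(2), atol=1e-6)

    def test_centroids_at_origin(self, rng):
        shapes = contour_population(6, rng)
        aligned = generalized_procrustes(shapes)
        np.testing.assert_allclose(aligned.shapes.mean(axis=1), 0.0,
                                   atol=1e-10)

    def test_scale_removed_when_requested(self, rng):
        shapes = contour_population(6, rng, size_cv=0.3)
        aligned = generalized_procrustes(shapes, retain_scale=False)
        sizes = [centroid_size(s) for s in aligned.shapes]
        np.testing.assert_allclose(sizes, 1.0, rtol=1e-9)

    def test_needs_two_shapes(self, rng):
        with pytest.raises(ValueError):
            generalized_procrustes(contour_population(1, rng))


class TestPointDistributionModel:
    def test_pure_scale_family_is_one_mode(self, rng):
        base = contour_population(1, rng, noise=0.0)[0]
        base = base - base.mean(0)
        shapes = np.stack([base * s for s in rng.uniform(0.7, 1.4, 12)])
        pdm = PointDistributionModel().fit(shapes)
        ratio = pdm.eigenvalues_[0] / pdm.eigenvalues_.sum()
        assert ratio > 0.99

    def test_full_reconstruction(self, rng):
        shapes = generalized_procrustes(
            contour_population(9, rng, noise=0.02)).shapes
        pdm = PointDistributionModel().fit(shapes)
        scores = pdm.transform(shapes)
        back = pdm.inverse_transform(scores)
        np.testing.assert_allclose(back, shapes, atol=1e-9)

    def test_eigenvalues_match_dense_eigensolver_oracle(self, rng):
        shapes = generalized_procrustes(
            contour_population(12, rng, noise=0.03)).shapes
        pdm = PointDistributionModel().fit(shapes)
        flat = shapes.reshape(len(shapes), -1)
        cov = np.cov(flat, rowvar=False, ddof=1)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = len(pdm.eigenvalues_)
        np.testing.assert_allclose(pdm.eigenvalues_, oracle[:k], atol=1e-10)
        assert pdm.eigenvalues_.sum() == pytest.approx(np.trace(cov) *
                                                       (1 - 0), rel=1e-6)

    def test_modes_orthonormal_and_sorted(self, rng):
        shapes = generalized_procrustes(
            contour_population(10, rng, noise=0.03)).shapes
        pdm = PointDistributionModel().fit(shapes)
        gram = pdm.modes_ @ pdm.modes_.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-10)
        assert (np.diff(pdm.eigenvalues_) <= 1e-12).all()

    def test_mean_shape_projects_to_zero(self, rng):
        shapes = generalized_procrustes(
            contour_population(8, rng, noise=0.02)).shapes
        pdm = PointDistributionModel().fit(shapes)
        np.testing.assert_allclose(pdm.transform(pdm.mean_shape_), 0.0,
                                   atol=1e-10)

    def test_standardized_unit_score(self, rng):
        shapes = generalized_procrustes(
            contour_population(8, rng, noise=0.02)).shapes
        pdm = PointDistributionModel().fit(shapes)
        shape2 = pdm.mean_shape_ + 3 * np.sqrt(pdm.eigenvalues_[1]) * \
            pdm.modes_[1].reshape(pdm.mean_shape_.shape)
        s = pdm.transform(shape2, standardized=True)
        assert s[1] == pytest.approx(3.0, abs=1e-8)
        assert np.max(np.abs(np.delete(s, 1))) < 1e-8

    def test_residual_orthogonal_to_retained_modes(self, rng):
        shapes = generalized_procrustes(
            contour_population(12, rng, noise=0.03)).shapes
        pdm = PointDistributionModel(n_modes=3).fit(shapes)
        target = shapes[0]
        recon = pdm.inverse_transform(pdm.transform(target))
        resid = (target - recon).reshape(-1)
        assert np.max(np.abs(pdm.modes_ @ resid)) < 1e-9

    def test_reconstruct_zero_scores_is_mean(self, rng):
        shapes = generalized_procrustes(
            contour_population(8, rng, noise=0.02)).shapes
        pdm = PointDistributionModel().fit(shapes)
        np.testing.assert_allclose(pdm.reconstruct(np.zeros(3)),
                                   pdm.mean_shape_, atol=1e-12)

    def test_plus_minus_three_sd_average_to_mean(self, rng):
        shapes = generalized_procrustes(
            contour_population(8, rng, noise=0.02)).shapes
        pdm = PointDistributionModel().fit(shapes)
        w = np.array([0.0, 1.0, 0.5])
        up = pdm.reconstruct(w, sd_multiple=3.0)
        dn = pdm.reconstruct(w, sd_multiple=-3.0)
        np.testing.assert_allclose(0.5 * (up + dn), pdm.mean_shape_,
                                   atol=1e-12)

    def test_mode1_tracks_size_when_size_variance_dominates(self, rng):
        shapes = contour_population(80, rng, g_sd=0.05, size_cv=0.25,
                                    noise=0.01)
        aligned = generalized_procrustes(shapes)
        pdm = PointDistributionModel().fit(aligned.shapes)
        scores = pdm.transform(aligned.shapes)
        sizes = np.array([centroid_size(s) for s in aligned.shapes])
        assert np.corrcoef(scores[:, 0], sizes)[0, 1] > 0.99


class TestGroupTests:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.normal(size=(20, 4))
        scores = np.vstack([x, x])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        p = per_mode_group_test(scores, labels)
        np.testing.assert_allclose(p, 1.0, atol=1e-12)

    def test_two_sd_shift_detected(self, rng):
        a = rng.normal(size=(50, 5))
        b = rng.normal(size=(50, 5))
        b[:, 1] += 2.0
        p = per_mode_group_test(np.vstack([a, b]),
                                np.array(["a"] * 50 + ["b"] * 50))
        assert p[1] < 1e-3
        assert (p[[0, 2, 3, 4]] > 1e-3).all()

    def test_matches_permutation_oracle_small_n(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        p = per_mode_group_test(np.column_stack([np.concatenate([a, b])]),
                                np.array(["a"] * 10 + ["b"] * 10))[0]
        pooled = np.concatenate([a, b])
        t_obs = abs(sps.ttest_ind(a, b, equal_var=False).statistic)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t = abs(sps.ttest_ind(perm[:10], perm[10:],
                                  equal_var=False).statistic)
            count += t >= t_obs
        p_perm = (count + 1) / (n_perm + 1)
        assert p == pytest.approx(p_perm, abs=0.03)

    def test_zero_variance_mode_raises(self):
        scores = np.zeros((10, 2))
        scores[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="zero variance"):
            per_mode_group_test(scores, np.array(["a"] * 5 + ["b"] * 5))


class TestLDA:
    def test_separable_point_masses_auc_one(self):
        scores = np.array([[0.0, 0.0], [0.1, 0.0],
                           [5.0, 0.0], [5.1, 0.0]])
        labels = np.array(["term", "term", "preterm", "preterm"])
        lda = train_lda(scores, labels, (1, 2), positive_class="preterm")
        assert lda.auc_ == 1.0
        assert (lda.predict(scores) == labels).all()

    def test_permuted_labels_auc_near_half(self, rng):
        scores = rng.normal(size=(200, 4))
        labels = rng.permutation(np.array(["a"] * 100 + ["b"] * 100))
        lda = train_lda(scores, labels, (1, 2, 3, 4))
        assert 0.4 < lda.auc_ < 0.65  # resubstitution optimism allowed
        assert 0.35 < loo_auc(scores, labels, (1, 2, 3, 4)) < 0.65

    def test_1d_subset_reduces_to_mean_difference_over_variance(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        scores = np.concatenate([a, b])[:, None]
        labels = np.array(["a"] * 40 + ["b"] * 40)
        lda = train_lda(np.column_stack([scores]), labels, (1,),
                        positive_class="b")
        pooled = ((39 * a.var(ddof=1) + 39 * b.var(ddof=1)) / 78)
        expected = (b.mean() - a.mean()) / pooled
        assert lda.coef_[0] == pytest.approx(expected, rel=1e-4)

    def test_direction_matches_sklearn_oracle(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x = rng.normal(size=(120, 5))
        x[:60] += np.array([0.5, -0.3, 0.2, 0.0, 0.1])
        labels = np.array(["pos"] * 60 + ["neg"] * 60)
        mine = train_lda(x, labels, (1, 2, 3, 4, 5), positive_class="pos")
        ref = LinearDiscriminantAnalysis().fit(x, labels)
        w_ref = ref.coef_.ravel()
        # sklearn orients toward its classes_[1]; compare directions
        cos = np.dot(mine.coef_, w_ref) / (np.linalg.norm(mine.coef_)
                                           * np.linalg.norm(w_ref))
        assert abs(cos) > 0.999

    def test_missing_class_raises(self, rng):
        with pytest.raises(ValueError):
            train_lda(rng.normal(size=(10, 2)), np.array(["a"] * 10), (1, 2))

    def test_loo_auc_bounded_by_resubstitution(self, rng):
        x = rng.normal(size=(80, 3))
        x[:40, 0] += 1.0
        labels = np.array(["a"] * 40 + ["b"] * 40)
        lda = train_lda(x, labels, (1, 2, 3), positive_class="a")
        assert loo_auc(x, labels, (1, 2, 3),
                       positive_class="a") <= lda.auc_ + 0.02


class TestModeSubsetSelection:
    def test_recovers_signal_modes_2_to_6(self, rng):
        n = 120
        scores = rng.normal(size=(2 * n, 8))
        scores[:n, 1:6] += 1.0  # shift modes 2..6 for the positive group
        labels = np.array(["preterm"] * n + ["term"] * n)
        subset, curve = select_mode_subset(scores, labels, max_mode=8,
                                           positive_class="preterm")
        assert subset == (2, 3, 4, 5, 6)
        aucs = dict(curve)
        assert aucs[(2, 3, 4, 5, 6)] > 0.85

    def test_null_returns_smallest_subset(self, rng):
        scores = rng.normal(size=(60, 6))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        subset, curve = select_mode_subset(scores, labels, max_mode=6)
        for _, a in curve:
            assert 0.3 < a < 0.7
        assert subset == (2,)

    def test_curve_loo_never_far_above_resub(self, rng):
        n = 60
        scores = rng.normal(size=(2 * n, 6))
        scores[:n, 1] += 1.2
        labels = np.array(["a"] * n + ["b"] * n)
        _, curve = select_mode_subset(scores, labels, max_mode=6,
                                      positive_class="a")
        for subset, a in curve:
            lda = train_lda(scores, labels, subset, positive_class="a")
            assert a <= lda.auc_ + 0.02

    def test_max_mode_validation(self, rng):
        with pytest.raises(ValueError):
            select_mode_subset(rng.normal(size=(10, 4)),
                               np.array(["a"] * 5 + ["b"] * 5), max_mode=9)


def test_mann_whitney_auc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    pos = rng.normal(0.5, 1, 30)
    neg = rng.normal(0.0, 1, 40)
    mine = mann_whitney_auc(pos, neg)
    ref = roc_auc_score([1] * 30 + [0] * 40, np.concatenate([pos, neg]))
    assert mine == pytest.approx(ref, abs=1e-12)


def test_end_to_end_birth_shift_followup_null(small_cfg):
    """Globularity shift at birth separates groups; follow-up does not."""
    from neocardio.cohort import generate_cohort

    cohort = generate_cohort(small_cfg, 21)
    sub = cohort.subjects.set_index("subject_id")
    keys = sorted(cohort.contours)
    shapes = np.stack([cohort.contours[k][0].points for k in keys])
    labels = np.array([sub.loc[k[0], "group"] for k in keys])
    stages = np.array([k[1] for k in keys])
    aligned = generalized_procrustes(shapes)
    pdm = PointDistributionModel(n_modes=6).fit(aligned.shapes)
    scores = pdm.transform(aligned.shapes, standardized=True)
    p_birth = per_mode_group_test(scores[stages == "birth"],
                                  labels[stages == "birth"])
    p_fu = per_mode_group_test(scores[stages == "followup"],
                               labels[stages == "followup"])
    assert p_birth[1] < 1e-3  # globularity mode separates groups at birth
    assert p_fu[1] > 0.01  # converged by follow-up
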