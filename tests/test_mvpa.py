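import dataclasses

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import midecode as md
from midecode import mvpa


def make_noise_patterns(rng, n_runs=6, n_voxels=27):
    labels = np.tile(md.IMAGERY_CONDITIONS, n_runs)
    runs = np.repeat(np.arange(n_runs), 3)
    X = rng.normal(size=(3 * n_runs, n_voxels))
    return mvpa.PatternSet(X=X, labels=labels, runs=runs, roi_name="test")


def make_separable_patterns(rng, n_runs=6, n_voxels=27, sep=50.0, noise=0.01):
    centers = {c: sep * rng.normal(size=n_voxels)
               for c in md.IMAGERY_CONDITIONS}
    rows, labels, runs = [], [], []
    for r in range(n_runs):
        for c in md.IMAGERY_CONDITIONS:
            rows.append(centers[c] + noise * rng.normal(size=n_voxels))
            labels.append(c)
            runs.append(r)
    return mvpa.PatternSet(X=np.array(rows), labels=np.array(labels),
                           runs=np.array(runs))


class TestExtractPatterns:
    def test_shape_and_row_order(self, subject_maps, tiny_atlas, tiny_config):
        atlas, _ = tiny_atlas
        ps = mvpa.extract_patterns(subject_maps, atlas, 1)
        assert ps.X.shape == (3 * tiny_config.n_runs, 27)
        # rows ordered run-major with the fixed condition order inside
        assert list(ps.labels[:3]) == list(md.IMAGERY_CONDITIONS)
        assert list(ps.runs[:6]) == [0, 0, 0, 1, 1, 1]

    def test_single_voxel_roi(self, subject_maps, tiny_atlas, tiny_config):
        atlas, _ = tiny_atlas
        single = md.AtlasVolume(
            md.Volume3D(np.where(np.indices(atlas.labels.data.shape).sum(0) == 0,
                                 1, 0).astype(int), atlas.labels.affine),
            {1: ("one", "L")})
        ps = mvpa.extract_patterns(subject_maps, single, 1)
        assert ps.X.shape == (3 * tiny_config.n_runs, 1)

    def test_empty_roi_rejected(self, subject_maps, tiny_atlas):
        atlas, _ = tiny_atlas
        with pytest.raises(ValueError, match="empty"):
            mvpa.extract_patterns(subject_maps, atlas, 99)

    def test_mismatched_grid_rejected(self, subject_maps):
        small, _ = md.make_atlas((9, 9, 9))
        with pytest.raises(ValueError, match="grid"):
            mvpa.extract_patterns(subject_maps, small, 1)

    def test_degenerate_voxels_dropped_consistently(self, subject_maps,
                                                    tiny_atlas):
        atlas, _ = tiny_atlas
        maps = [dataclasses.replace(m) for m in subject_maps]
        flag = np.zeros(maps[0].t.data.shape, dtype=bool)
        flag[1, 1, 1] = True  # voxel inside ROI 1
        maps[0] = dataclasses.replace(maps[0], degenerate=flag)
        ps = mvpa.extract_patterns(maps, atlas, 1)
        assert ps.X.shape[1] == 26


class TestMeanCenter:
    def test_constant_row_becomes_zero(self):
        ps = mvpa.PatternSet(X=np.full((2, 5), 3.0),
                             labels=np.array(["aiming", "squeezing"]),
                             runs=np.array([0, 0]))
        np.testing.assert_array_equal(mvpa.mean_center(ps).X, 0.0)

    def test_offset_invariance_and_idempotence(self, rng):
        ps = make_noise_patterns(rng)
        shifted = mvpa.PatternSet(X=ps.X + 7.5, labels=ps.labels, runs=ps.runs)
        c1 = mvpa.mean_center(ps)
        c2 = mvpa.mean_center(shifted)
        np.testing.assert_allclose(c1.X, c2.X, atol=1e-12)
        np.testing.assert_allclose(mvpa.mean_center(c1).X, c1.X, atol=1e-12)
        assert np.abs(c1.X.mean(axis=1)).max() < 1e-12


class TestPca:
    def test_rank_two_data_has_no_higher_variance(self, rng):
        base = rng.normal(size=(2, 30))
        coeff = rng.normal(size=(12, 2))
        X = coeff @ base
        model = mvpa.fit_pca(X, 5)
        assert model.explained_variance[2:].max() < 1e-10

    def test_top5_variance_matches_dense_eigendecomposition(self, rng):
        X = rng.normal(size=(40, 60))
        scores = mvpa.pca_reduce(mvpa.PatternSet(
            X=X, labels=np.array(["a"] * 40), runs=np.zeros(40, int)), 5)
        got = scores.var(axis=0, ddof=1).sum()
        cov = np.cov(X, rowvar=False)
        eigvals = np.linalg.eigvalsh(cov)  # independent dense eigensolver
        expected = eigvals[-5:].sum()
        assert abs(got - expected) < 1e-8

    def test_components_orthonormal(self, rng):
        model = mvpa.fit_pca(rng.normal(size=(20, 50)), 5)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(20, 30))
        model = mvpa.fit_pca(X, 5)
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_matches_sklearn_scores(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.normal(size=(30, 40))
        ours = mvpa.pca_transform(mvpa.fit_pca(X, 5), X)
        theirs = sklearn_pca(n_components=5, svd_solver="full").fit_transform(X)
        # agree up to per-component sign
        for j in range(5):
            assert (np.allclose(ours[:, j], theirs[:, j], atol=1e-8)
                    or np.allclose(ours[:, j], -theirs[:, j], atol=1e-8))

    def test_rank_deficit_pads_and_warns(self, rng):
        X = rng.normal(size=(5, 2))  # rank <= 2 after centering
        with pytest.warns(UserWarning, match="pad"):
            scores = mvpa.pca_transform(mvpa.fit_pca(X, 5), X)
        assert scores.shape == (5, 5)
        assert np.all(scores[:, 2:] == 0.0)

    def test_zero_voxels_rejected(self):
        with pytest.raises(ValueError):
            mvpa.fit_pca(np.empty((10, 0)), 5)


class TestLda:
    def test_one_dimensional_nearest_mean(self):
        F = np.array([[-0.2], [0.2], [1.8], [2.2]])
        y = np.array(["lo", "lo", "hi", "hi"])
        model = mvpa.lda_fit(F, y)
        assert mvpa.lda_predict(model, np.array([[0.9]]))[0] == "lo"
        assert mvpa.lda_predict(model, np.array([[1.1]]))[0] == "hi"

    def test_matches_gaussian_bayes_rule_oracle(self, rng):
        """Predictions equal a brute-force equal-covariance Bayes rule."""
        means = {"aiming": np.array([0.0, 0.0]),
                 "squeezing": np.array([2.0, 0.5]),
                 "extflex": np.array([0.5, 2.0])}
        F, y = [], []
        for c, mu in means.items():
            F.append(mu + rng.normal(size=(10, 2)))
            y += [c] * 10
        F = np.vstack(F)
        y = np.array(y)
        model = mvpa.lda_fit(F, y, ridge=0.0)

        # oracle: evaluate the pooled-covariance Gaussian density per class
        classes = model.classes
        mus = {c: F[y == c].mean(axis=0) for c in classes}
        pooled = sum((F[y == c] - mus[c]).T @ (F[y == c] - mus[c])
                     for c in classes) / (len(F) - len(classes))
        test_points = rng.normal(scale=2.0, size=(200, 2))
        expected = []
        for x in test_points:
            dens = [multivariate_normal.pdf(x, mus[c], pooled) * (1 / 3)
                    for c in classes]
            expected.append(classes[int(np.argmax(dens))])
        got = mvpa.lda_predict(model, test_points)
        assert list(got) == expected

    def test_duplicating_samples_keeps_boundary(self, rng):
        F = rng.normal(size=(12, 3)) + np.repeat([[0], [2]], 6, axis=0)
        y = np.repeat(["a", "b"], 6)
        m1 = mvpa.lda_fit(F, y)
        m2 = mvpa.lda_fit(np.vstack([F, F]), np.concatenate([y, y]))
        pts = rng.normal(size=(50, 3))
        assert list(mvpa.lda_predict(m1, pts)) == list(mvpa.lda_predict(m2, pts))

    def test_singular_covariance_without_ridge(self):
        F = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 6.0], [3.0, 6.0]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="ridge"):
            mvpa.lda_fit(F, y, ridge=0.0)

    def test_small_classes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mvpa.lda_fit(np.zeros((3, 2)), np.array(["a", "a", "b"]))

    def test_matches_sklearn_lda(self, rng):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        F = rng.normal(size=(60, 4))
        F[:20] += 2.0
        F[20:40] -= 2.0
        y = np.repeat(["a", "b", "c"], 20)
        ours = mvpa.lda_predict(mvpa.lda_fit(F, y, ridge=0.0), F)
        theirs = sk.LinearDiscriminantAnalysis(solver="lsqr").fit(F, y).predict(F)
        assert (np.asarray(ours) == np.asarray(theirs)).all()


class TestLoroCv:
    def test_separable_patterns_decode_perfectly(self, rng):
        ps = make_separable_patterns(rng)
        res = mvpa.loro_cv(ps)
        assert res.accuracy == 1.0

    def test_fold_bookkeeping(self, rng):
        ps = make_noise_patterns(rng, n_runs=20)
        res = mvpa.loro_cv(ps)
        assert res.n_total == 60
        assert sorted(res.assignments["run"].unique()) == list(range(20))
        assert (res.assignments.groupby("run").size() == 3).all()

    def test_chance_level_on_label_permuted_patterns(self):
        """Null patterns decode at chance: the 95% CI of the mean accuracy
        over simulated subjects covers 1/3."""
        accs = []
        for subject in range(40):
            rng = np.random.default_rng(1000 + subject)
            ps = make_noise_patterns(rng, n_runs=10)
            perm_labels = ps.labels.copy()
            for r in range(10):
                idx = np.where(ps.runs == r)[0]
                perm_labels[idx] = perm_labels[rng.permutation(idx)]
            ps = mvpa.PatternSet(X=ps.X, labels=perm_labels, runs=ps.runs)
            accs.append(mvpa.loro_cv(ps).accuracy)
        mean = np.mean(accs)
        half = 1.96 * np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert mean - half <= 1 / 3 <= mean + half

    def test_missing_condition_in_run_rejected(self, rng):
        ps = make_noise_patterns(rng)
        labels = ps.labels.copy()
        labels[0] = "squeezing"  # run 0 now lacks 'aiming'
        bad = mvpa.PatternSet(X=ps.X, labels=labels, runs=ps.runs)
        with pytest.raises(ValueError, match="missing"):
            mvpa.loro_cv(bad)

    def test_two_runs_required(self, rng):
        ps = make_noise_patterns(rng, n_runs=1)
        with pytest.raises(ValueError, match="2 runs"):
            mvpa.loro_cv(ps)

    def test_voxel_permutation_invariance(self, rng):
        ps = make_noise_patterns(rng)
        perm = rng.permutation(ps.X.shape[1])
        permuted = mvpa.PatternSet(X=ps.X[:, perm], labels=ps.labels,
                                   runs=ps.runs)
        assert mvpa.loro_cv(ps).accuracy == mvpa.loro_cv(permuted).accuracy

    def test_mean_centered_invariant_to_per_sample_offsets(self, rng):
        ps = make_noise_patterns(rng)
        offsets = rng.normal(scale=10.0, size=(len(ps.X), 1))
        shifted = mvpa.PatternSet(X=ps.X + offsets, labels=ps.labels,
                                  runs=ps.runs)
        a = mvpa.loro_cv(mvpa.mean_center(ps)).accuracy
        b = mvpa.loro_cv(mvpa.mean_center(shifted)).accuracy
        assert a == b

    def test_pca_within_fold_never_sees_test_rows(self, rng, monkeypatch):
        ps = make_noise_patterns(rng, n_runs=6)
        seen_sizes = []
        real_fit = mvpa.fit_pca

        def spy(X, n_components=5):
            seen_sizes.append(len(X))
            return real_fit(X, n_components)

        monkeypatch.setattr(mvpa, "fit_pca", spy)
        mvpa.loro_cv(ps, pca_within_fold=True)
        # one fit per fold, each on the 3 * (n_runs - 1) training rows only
        assert seen_sizes == [15] * 6


class TestDecodeAllRois:
    def test_all_rois_both_variants(self, subject_maps, tiny_atlas, tiny_config):
        atlas, _ = tiny_atlas
        table = md.decode_all_rois(subject_maps, atlas, tiny_config)
        assert len(table) == 2 * len(atlas.roi_labels)
        assert set(table["variant"]) == {"raw", "mean_centered"}
        assert ((table["accuracy"] >= 0) & (table["accuracy"] <= 1)).all()
        assert (table["n_total"] == 3 * tiny_config.n_runs).all()
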