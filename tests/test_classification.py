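"""LDA, repeated cross-validation, shuffle nulls, and feature subsets."""

import numpy as np
import pytest

import fearetho as fe
from fearetho.classify import stratified_folds, subset_arrays

KEY_SEED = 5


class FakeIdentityRng:
    """Stands in for a Generator whose permutation is the identity."""

    def permutation(self, n):
        return np.arange(n)


class TestFitLda:
    def closed_form_data(self):
        X = np.array(
            [[1.0, 0], [-1, 0], [0, 1], [0, -1], [3, 0], [1, 0], [2, 1], [2, -1]]
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        return X, y

    def test_closed_form_two_gaussian_solution(self):
        """Means (0,0)/(2,0), pooled covariance 2/3 I -> w along x1,
        boundary at x1 = 1; (0.9, 5) falls on the class-0 side."""
        X, y = self.closed_form_data()
        m = fe.fit_lda(X, y)
        assert m.w[1] == pytest.approx(0.0, abs=1e-12)
        assert m.w[0] == pytest.approx(3.0, rel=1e-12)
        assert -m.b / m.w[0] == pytest.approx(1.0, rel=1e-12)
        assert m.predict(np.array([[0.9, 5.0]]))[0] == 0

    def test_degenerate_duplicated_points_train_perfectly(self):
        X = np.array([[0.0, 0.0]] * 4 + [[1.0, 1.0]] * 4)
        y = np.array(["a"] * 4 + ["b"] * 4)
        m = fe.fit_lda(X, y)
        assert (m.predict(X) == y).all()

    def test_economy_path_equals_brute_force_pinv(self):
        """The low-rank SVD route reproduces pinv(S) @ d exactly (p > n)."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 50))
        y = np.array(["a"] * 10 + ["b"] * 10)
        m = fe.fit_lda(X, y)
        mus = np.stack([X[y == c].mean(axis=0) for c in ("a", "b")])
        Xc = np.concatenate([X[y == c] - mu for c, mu in zip(("a", "b"), mus)])
        S = Xc.T @ Xc / (len(X) - 2)
        w_ref = np.linalg.pinv(S) @ (mus[1] - mus[0])
        np.testing.assert_allclose(m.w, w_ref, atol=1e-10)

    @pytest.mark.parametrize(
        "X,y,err",
        [
            (np.zeros((4, 2)), ["a"] * 4, "2 classes"),
            (np.full((4, 2), np.nan), ["a", "a", "b", "b"], "finite"),
            (np.zeros((3, 2)), ["a", "b", "b"], "at least 2"),
        ],
    )
    def test_invalid_inputs_raise(self, X, y, err):
        with pytest.raises(ValueError, match=err):
            fe.fit_lda(X, y)

    def test_sklearn_oracle_agreement_on_separable_table(self):
        """Pseudo-inverse LDA agrees with an independent reference
        discriminant on >= 95% of held-out sessions (64 x 1044 table)."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        ds = fe.simulate_experiment(fe.SimConfig(seed=2, effect_size="strong"))
        arrays, y, _ = fe.stack_sessions(fe.session_arrays(ds.trials))
        X = fe.subset_features(arrays)
        rng = np.random.default_rng(0)
        agree = total = 0
        for _ in range(3):
            folds = stratified_folds(y, 10, rng)
            for f in range(10):
                test = folds == f
                mine = fe.fit_lda(X[~test], y[~test])
                ref = sklearn_da.LinearDiscriminantAnalysis(solver="svd").fit(
                    X[~test], y[~test]
                )
                agree += (mine.predict(X[test]) == ref.predict(X[test])).sum()
                total += test.sum()
        assert agree / total >= 0.95

    def test_prediction_invariant_to_feature_order_and_affine_map(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        y = np.array(["a", "b"] * 20)
        X[y == "a"] += 0.7
        probe = rng.normal(size=(15, 6))
        base = fe.fit_lda(X, y).predict(probe)
        perm = rng.permutation(6)
        assert (fe.fit_lda(X[:, perm], y).predict(probe[:, perm]) == base).all()
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)  # invertible
        shift = rng.normal(size=6)
        assert (fe.fit_lda(X @ A + shift, y).predict(probe @ A + shift) == base).all()


class TestRepeatedCv:
    def test_separable_clusters_reach_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (32, 5)), rng.normal(10, 0.1, (32, 5))])
        y = np.array(["a"] * 32 + ["b"] * 32)
        res = fe.repeated_cv(X, y, reps=5, seed=KEY_SEED)
        assert res.mean == 1.0

    def test_identical_rows_with_random_labels_stay_at_chance(self):
        X = np.ones((32, 4))
        rng = np.random.default_rng(2)
        y = rng.permutation(np.array(["a", "b"] * 16))
        res = fe.repeated_cv(X, y, k=4, reps=20, seed=KEY_SEED)
        assert abs(res.mean - 0.5) <= 3 * max(res.sem, 1e-12) + 1e-12

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 8))
        y = np.array(["a", "b"] * 12)
        r1 = fe.repeated_cv(X, y, k=4, reps=10, seed=KEY_SEED)
        r2 = fe.repeated_cv(X, y, k=4, reps=10, seed=KEY_SEED)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)

    def test_mean_sem_recomputable_from_accuracies(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 8))
        y = np.array(["a", "b"] * 12)
        res = fe.repeated_cv(X, y, k=4, reps=10, seed=KEY_SEED)
        assert res.mean == np.mean(res.accuracies)
        assert res.sem == pytest.approx(
            np.std(res.accuracies, ddof=1) / np.sqrt(len(res.accuracies))
        )
        assert ((0 <= res.accuracies) & (res.accuracies <= 1)).all()

    def test_k_below_two_raises(self):
        with pytest.raises(ValueError):
            fe.repeated_cv(np.zeros((4, 2)), ["a", "a", "b", "b"], k=1)

    def test_training_accuracy_well_above_chance(self, session_stack):
        """Pseudo-inverse LDA restricts w to the within-scatter range, so
        with n << p it does NOT separate its own training set perfectly
        (the mean-difference component in the scatter null space is
        annihilated); training accuracy is nonetheless far above chance.
        Held-out accuracy can legitimately exceed it on these data."""
        arrays, y, _ = session_stack
        X = fe.subset_features(arrays)
        model = fe.fit_lda(X, y)
        train_acc = float(np.mean(model.predict(X) == y))
        assert train_acc > 0.75


class TestShuffles:
    def test_session_shuffle_preserves_label_multiset(self, rng):
        y = np.array(["paired"] * 32 + ["unpaired"] * 32)
        ys = fe.session_shuffle(y, rng)
        assert sorted(ys) == sorted(y)

    def test_session_shuffle_fixed_point_fraction(self):
        """Balanced binary labels: expected agreement with the original
        vector under a uniform permutation is 1/2."""
        y = np.array(["p"] * 32 + ["u"] * 32)
        rng = np.random.default_rng(6)
        frac = np.mean(
            [(fe.session_shuffle(y, rng) == y).mean() for _ in range(10_000)]
        )
        assert abs(frac - 0.5) < 0.02

    def test_session_shuffle_seeded_reproducible(self):
        y = np.arange(20)
        a = fe.session_shuffle(y, np.random.default_rng(9))
        b = fe.session_shuffle(y, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_temporal_shuffle_preserves_row_sums(self, session_stack, rng):
        arrays, _, _ = session_stack
        shuffled = fe.temporal_shuffle(arrays, rng)
        np.testing.assert_allclose(
            shuffled.sum(axis=2), arrays.sum(axis=2), atol=1e-12
        )
        assert shuffled.shape == arrays.shape

    def test_temporal_shuffle_identity_permutation(self, session_stack):
        arrays, _, _ = session_stack
        out = fe.temporal_shuffle(arrays, FakeIdentityRng())
        np.testing.assert_array_equal(out, arrays)

    def test_temporal_shuffle_rejects_flattened_input(self, rng):
        with pytest.raises(ValueError, match="unflattened"):
            fe.temporal_shuffle(np.zeros((4, 1044)), rng)

    def test_temporal_shuffle_keeps_accuracy_when_time_uninformative(self):
        """When group information lives purely in behavior totals (labels
        drawn i.i.d. over frames), losing temporal order costs nothing."""
        rng = np.random.default_rng(12)
        n_per = 24
        arrays = np.zeros((2 * n_per, 12, 87))
        probs = {
            "p": np.array([0.30, 0.05, 0.15, 0.05, 0.05, 0.02, 0.02, 0.16, 0.05, 0.05, 0.05, 0.05]),
            "u": np.array([0.05, 0.05, 0.25, 0.15, 0.10, 0.05, 0.02, 0.03, 0.05, 0.10, 0.10, 0.05]),
        }
        y = np.array(["p"] * n_per + ["u"] * n_per)
        for i, lab in enumerate(y):
            draws = rng.choice(12, size=87, p=probs[lab])
            arrays[i, draws, np.arange(87)] = 1.0
        intact = fe.repeated_cv(arrays.reshape(len(y), -1), y, reps=20, seed=KEY_SEED)
        # average over shuffle realizations: a single permutation draw adds
        # realization noise that the per-repetition SEM does not capture
        real_means = []
        for _ in range(5):
            shuffled_arrays = fe.temporal_shuffle(arrays, rng)
            res = fe.repeated_cv(
                shuffled_arrays.reshape(len(y), -1), y, reps=10, seed=KEY_SEED
            )
            real_means.append(res.mean)
        spread = np.std(real_means, ddof=1) / np.sqrt(len(real_means))
        gap = abs(intact.mean - np.mean(real_means))
        assert gap <= 3 * (intact.sem + spread) + 0.02


class TestSubsets:
    def test_identity_subset_is_1044(self, session_stack):
        arrays, _, _ = session_stack
        assert fe.subset_features(arrays).shape[1] == 1044

    @pytest.mark.parametrize(
        "period,cat,n",
        [
            ("cue", "Immobile", 100),
            ("cue", "Horizontal", 100),
            ("cue", "Vertical", 250),
            ("cue", "Reward", 100),
            ("post", "Vertical", 60),
        ],
    )
    def test_subset_feature_counts(self, session_stack, period, cat, n):
        arrays, _, _ = session_stack
        assert fe.subset_features(arrays, period=period, categories=cat).shape[1] == n

    def test_groom_survives_no_category(self):
        arrays = np.zeros((2, 12, 87))
        arrays[:, fe.BEHAVIORS.index("groom"), :] = 7.0
        for cat in fe.CATEGORIES:
            assert (fe.subset_features(arrays, categories=cat) != 7.0).all()

    def test_unknown_subset_raises(self, session_stack):
        arrays, _, _ = session_stack
        with pytest.raises(ValueError):
            fe.subset_features(arrays, period="shock")
        with pytest.raises(ValueError):
            fe.subset_features(arrays, categories="Grooming")

    def test_subset_arrays_shape(self, session_stack):
        arrays, _, _ = session_stack
        assert subset_arrays(arrays, "cue", "Immobile").shape == (64, 2, 50)


class TestFullAnalysis:
    def test_null_dataset_stays_at_chance(self):
        """With identical generative parameters for both groups the intact
        classifier sits at chance."""
        ds = fe.simulate_experiment(fe.SimConfig(seed=4, effect_size="none"))
        arrays, y, _ = fe.stack_sessions(fe.session_arrays(ds.trials))
        res = fe.repeated_cv(fe.subset_features(arrays), y, reps=20, seed=KEY_SEED)
        assert abs(res.mean - 0.5) <= 3 * res.sem + 0.05

    def test_grid_summary_structure(self, session_stack):
        arrays, y, _ = session_stack
        grid = [("intact", "cue", "all"), ("session_shuffled", "all", "all")]
        summary, results = fe.run_full_analysis(arrays, y, seed=7, reps=5, grid=grid)
        assert list(summary["condition"]) == ["intact", "session_shuffled"]
        assert len(results) == 2
        assert (summary["mean_accuracy"].between(0, 1)).all()
        long = fe.classify.accuracies_long(results)
        assert len(long) == 2 * 5  # cells x repetitions

    def test_grid_deterministic_for_seed(self, session_stack):
        arrays, y, _ = session_stack
        grid = [("temporal_shuffled", "cue", "all")]
        s1, _ = fe.run_full_analysis(arrays, y, seed=7, reps=3, grid=grid)
        s2, _ = fe.run_full_analysis(arrays, y, seed=7, reps=3, grid=grid)
        assert s1.equals(s2)
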