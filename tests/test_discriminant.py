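"""Stepwise Mahalanobis MDA, LOOCV, Press's Q, potency, subsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stockid import (
    ClassificationTable,
    InsufficientDataError,
    SingularMatrixError,
    StepwiseDiscriminantAnalysis,
    fit_discriminant,
    loocv_confusion,
    mahalanobis_d2,
    potency_index,
    press_q,
    scatter_matrices,
    score_size_independence,
    stepwise_select,
    stratified_subsample,
)
from stockid.synthetic import generate_morphometrics

from conftest import small_config


# ---------------------------------------------------------------------------
# independent oracles (numpy-only, no package internals)
# ---------------------------------------------------------------------------

def _oracle_scatter(X, y):
    classes = sorted(set(y))
    W = np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        block = X[y == c]
        d = block - block.mean(axis=0)
        W += d.T @ d
    grand = X - X.mean(axis=0)
    T = grand.T @ grand
    return W, T, classes


def _oracle_wilks(X, y, subset):
    if not subset:
        return 1.0
    W, T, _ = _oracle_scatter(X[:, subset], y)
    return np.linalg.det(W) / np.linalg.det(T)


def _oracle_min_d2(X, y, subset):
    Xs = X[:, subset]
    W, _, classes = _oracle_scatter(Xs, y)
    S_inv = np.linalg.inv(W / (len(y) - len(classes)))
    means = [Xs[y == c].mean(axis=0) for c in classes]
    best = np.inf
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            d = means[i] - means[j]
            best = min(best, float(d @ S_inv @ d))
    return best


def oracle_stepwise(X, y, f_enter=3.84, f_remove=2.71):
    """Greedy-compatible exhaustive search: at each cardinality evaluate
    every candidate subset extension directly from fresh matrix algebra."""
    n = len(y)
    k = len(set(y))
    selected = []
    while True:
        lam_cur = _oracle_wilks(X, y, selected)
        candidates = []
        for v in range(X.shape[1]):
            if v in selected:
                continue
            lam_new = _oracle_wilks(X, y, selected + [v])
            ratio = lam_new / lam_cur
            df2 = n - k - len(selected)
            f_in = (df2 / (k - 1)) * (1 - ratio) / ratio
            if f_in >= f_enter:
                candidates.append((_oracle_min_d2(X, y, selected + [v]), v))
        if not candidates:
            break
        selected.append(max(candidates)[1])
        # removal sweep
        while len(selected) > 1:
            lam_full = _oracle_wilks(X, y, selected)
            worst = None
            worst_f = np.inf
            for v in selected:
                rest = [u for u in selected if u != v]
                ratio = lam_full / _oracle_wilks(X, y, rest)
                df2 = n - k - len(rest)
                f_out = (df2 / (k - 1)) * (1 - ratio) / ratio
                if f_out < worst_f:
                    worst, worst_f = v, f_out
            if worst_f >= f_remove:
                break
            selected.remove(worst)
    return selected


def oracle_nearest_mahalanobis(X_train, y_train, X_test):
    """Equal-prior Gaussian rule: nearest group mean in pooled metric."""
    W, _, classes = _oracle_scatter(X_train, y_train)
    S_inv = np.linalg.inv(W / (len(y_train) - len(classes)))
    means = {c: X_train[y_train == c].mean(axis=0) for c in classes}
    preds = []
    for x in np.atleast_2d(X_test):
        d2 = {c: (x - m) @ S_inv @ (x - m) for c, m in means.items()}
        preds.append(min(sorted(d2), key=lambda c: d2[c]))
    return np.array(preds)


# ---------------------------------------------------------------------------


class TestStratifiedSubsample:
    def _table(self, n=60):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "specimen_id": [f"s{i}" for i in range(n)],
            "group": ["g1"] * n,
            "river": rng.choice(["r1", "r2", "r3", "r4", "r5", "r6"], n),
            "sex": rng.choice(["m", "f"], n),
        })

    def test_full_target_identity(self):
        t = self._table()
        out = stratified_subsample(t, targets={"g1": len(t)}, seed=1)
        pd.testing.assert_frame_equal(out, t)

    def test_allocation_within_one_of_proportional(self):
        """Six rivers x two sexes reduced to 36: counts off by <= 1."""
        t = self._table(168)
        out = stratified_subsample(t, targets={"g1": 36}, seed=2)
        assert len(out) == 36
        full = t.groupby(["river", "sex"]).size()
        sub = out.groupby(["river", "sex"]).size().reindex(full.index,
                                                           fill_value=0)
        exact = 36 * full / full.sum()
        assert (np.abs(sub - exact) <= 1.0 + 1e-9).all()

    def test_deterministic_given_seed(self):
        t = self._table(100)
        a = stratified_subsample(t, targets={"g1": 40}, seed=7)
        b = stratified_subsample(t, targets={"g1": 40}, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestScatterAndD2:
    def test_single_group_between_scatter_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        W, B = scatter_matrices(X, np.repeat(["a"], 10))
        assert np.allclose(B, 0.0)

    def test_within_plus_between_equals_total(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = np.repeat(["a", "b"], 5)
        W, B = scatter_matrices(X, y)
        d = X - X.mean(axis=0)
        assert np.allclose(W + B, d.T @ d, atol=1e-10)

    def test_duplicated_column_raises(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(SingularMatrixError):
            scatter_matrices(X, np.repeat(["a", "b"], 6))

    def test_d2_equal_means_zero(self):
        assert mahalanobis_d2([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_d2_identity_cov_is_euclidean(self):
        assert mahalanobis_d2([3.0, 4.0], [0.0, 0.0], np.eye(2)) == \
            pytest.approx(25.0)

    def test_d2_hand_inverted_covariance(self):
        """S = [[2,1],[1,2]], d = (1,1): D2 = d' S^-1 d = 2/3."""
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert mahalanobis_d2([1.0, 1.0], [0.0, 0.0], S) == \
            pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_d2_non_pd_raises(self):
        with pytest.raises(SingularMatrixError):
            mahalanobis_d2([1.0, 0.0], [0.0, 0.0],
                           np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestStepwise:
    def test_pure_noise_mostly_empty_selection(self):
        """Under the null, nothing clears F-to-enter in >= 90% of runs."""
        empties = 0
        n_runs = 200
        y = np.repeat(["a", "b", "c"], 30)
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(90, 3))
            _, selected = stepwise_select(X, y)
            empties += len(selected) == 0
        assert empties >= 0.90 * n_runs

    def test_planted_signal_recovered_exactly(self):
        """Three informative characters (one distractor) are selected,
        and nothing else, in >= 95% of runs."""
        exact = 0
        n_runs = 100
        y = np.repeat(["a", "b", "c"], 25)
        # orthogonal separation directions so each variable contributes
        shift = np.array([
            [0.0, 0.0, 2.0],
            [2.0, 0.0, 0.0],
            [0.0, 2.0, 0.0],
        ])
        for seed in range(n_runs):
            rng = np.random.default_rng(2000 + seed)
            X = rng.normal(size=(75, 4))
            X[:, :3] += np.repeat(shift, 25, axis=0)
            _, selected = stepwise_select(X, y)
            exact += set(selected) == {0, 1, 2}
        assert exact >= 0.95 * n_runs

    @pytest.mark.parametrize("seed,p", [(0, 4), (1, 5), (2, 6), (3, 6)])
    def test_matches_exhaustive_oracle(self, seed, p):
        """Greedy trace equals the exhaustive-search oracle for p <= 6."""
        rng = np.random.default_rng(seed)
        y = np.repeat(["a", "b", "c"], 20)
        X = rng.normal(size=(60, p))
        X[:, 0] += np.repeat([0.0, 1.0, 2.0], 20)
        X[:, 1] += np.repeat([1.0, 0.0, 0.5], 20)
        _, selected = stepwise_select(X, y)
        assert selected == oracle_stepwise(X, y)


class TestFit:
    def test_two_groups_single_function_full_share(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        X[15:] += 2.0
        model = fit_discriminant(X, np.repeat(["a", "b"], 15))
        assert model.eigenvalues_.shape == (1,)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_unit_pooled_within_score_variance(self, three_group_blobs):
        X, y = three_group_blobs
        model = fit_discriminant(X, y)
        scores = model.transform(X)
        pooled = 0.0
        for c in model.classes_:
            d = scores[y == c] - scores[y == c].mean(axis=0)
            pooled += (d**2).sum(axis=0)
        pooled /= len(y) - len(model.classes_)
        assert np.allclose(pooled, 1.0, atol=1e-9)

    def test_eigenvalues_match_generalized_eigenproblem(self):
        """inv(W) @ B eigenvalues computed by explicit inversion."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(45, 2))
        X[15:30, 0] += 1.5
        X[30:, 1] += 2.0
        y = np.repeat(["a", "b", "c"], 15)
        W, _, _ = _oracle_scatter(X, y)
        d = X - X.mean(axis=0)
        B = d.T @ d - W
        ref = np.sort(np.linalg.eigvals(np.linalg.inv(W) @ B).real)[::-1]
        model = fit_discriminant(X, y)
        assert np.allclose(model.eigenvalues_, ref[:2], atol=1e-8)

    def test_scores_invariant_to_diagonal_affine_transform(self,
                                                           three_group_blobs):
        X, y = three_group_blobs
        a = fit_discriminant(X, y)
        X2 = X * np.array([2.0, 0.5, 7.0]) + np.array([1.0, -3.0, 0.0])
        b = fit_discriminant(X2, y)
        assert np.allclose(a.transform(X), b.transform(X2), atol=1e-8)

    def test_wilks_lambda_from_eigenvalues(self, three_group_blobs):
        X, y = three_group_blobs
        model = fit_discriminant(X, y)
        assert model.wilks_lambda_ == pytest.approx(
            np.prod(1.0 / (1.0 + model.eigenvalues_)), rel=1e-12
        )

    def test_matches_sklearn_lda_predictions(self, three_group_blobs):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = three_group_blobs
        model = fit_discriminant(X, y)
        ref = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, y)
        agree = (model.predict(X) == ref.predict(X)).mean()
        assert agree >= 0.99


class TestClassify:
    def test_centroid_maps_to_its_group(self, three_group_blobs):
        X, y = three_group_blobs
        model = fit_discriminant(X, y)
        # invert the score mapping at each centroid via least squares
        for i, c in enumerate(model.classes_):
            x = np.linalg.lstsq(
                model.scalings_.T,
                model.centroids_[i],
                rcond=None,
            )[0] + model.intercept_means_
            assert model.predict(x[None, :])[0] == c

    def test_tie_breaks_to_lowest_group_index(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        model = fit_discriminant(X, np.array(["a", "a", "a", "b", "b", "b"]))
        assert model.predict(np.array([[0.0]]))[0] == "a"

    def test_matches_bayes_rule_oracle(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        X = np.vstack([c + rng.normal(size=(30, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 30)
        model = fit_discriminant(X, y)
        grid = rng.normal(scale=2.5, size=(200, 2)) + 1.0
        ours = model.predict(grid)
        ref = oracle_nearest_mahalanobis(X, y, grid)
        assert (ours == ref).mean() >= 0.99

    def test_missing_variable_named(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                          "b": [2.0, 1.0, 3.0, 6.0, 5.0, 7.0]})
        model = fit_discriminant(X, np.repeat(["u", "v"], 3), selected=["b"])
        with pytest.raises(KeyError, match="b"):
            model.predict(pd.DataFrame({"a": [1.0]}))


class TestLoocv:
    def test_perfectly_separated_hundred_percent(self):
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.normal(0, 0.1, (10, 2)),
            rng.normal(10, 0.1, (10, 2)),
            rng.normal(20, 0.1, (10, 2)),
        ])
        y = np.repeat(["a", "b", "c"], 10)
        table = loocv_confusion(X, y)
        assert (table.percent_correct == 100.0).all()
        assert table.overall_percent == 100.0

    def test_matches_naive_refit_oracle(self):
        """12-specimen toy: identical table to per-fold Mahalanobis rule."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 2))
        X[4:8] += 1.5
        X[8:] += np.array([0.0, 3.0])
        y = np.repeat(["a", "b", "c"], 4)
        ours = loocv_confusion(X, y)
        mat = pd.DataFrame(0, index=["a", "b", "c"], columns=["a", "b", "c"])
        for i in range(12):
            mask = np.arange(12) != i
            pred = oracle_nearest_mahalanobis(X[mask], y[mask], X[i])[0]
            mat.loc[y[i], pred] += 1
        pd.testing.assert_frame_equal(ours.counts, mat)

    def test_small_group_raises(self):
        X = np.random.default_rng(9).normal(size=(7, 2))
        y = np.array(["a", "a", "a", "a", "a", "b", "b"])
        with pytest.raises(InsufficientDataError):
            loocv_confusion(X, y)


class TestPublishedTables:
    """Printed confusion tables are valid inputs for the scoring helpers."""

    MORPHO = pd.DataFrame(
        [[14, 11, 11], [7, 16, 5], [5, 1, 17]],
        index=["g1", "g2", "g3"], columns=["g1", "g2", "g3"],
    )
    FA = pd.DataFrame(
        [[26, 8, 2], [1, 17, 1], [0, 0, 19]],
        index=["g1", "g2", "g3"], columns=["g1", "g2", "g3"],
    )

    def test_morphometric_percent_correct(self):
        t = ClassificationTable.from_counts(self.MORPHO)
        assert t.overall_percent == pytest.approx(54.0, abs=0.05)
        assert np.allclose(t.percent_correct.round(1), [38.9, 57.1, 73.9])

    def test_fatty_acid_percent_correct(self):
        t = ClassificationTable.from_counts(self.FA)
        assert t.overall_percent == pytest.approx(83.8, abs=0.05)
        assert np.allclose(t.percent_correct.round(1), [72.2, 89.5, 100.0])

    def test_press_q_morphometric_table(self):
        q = press_q(ClassificationTable.from_counts(self.MORPHO))
        assert q.q == pytest.approx(16.759, abs=5e-4)
        assert q.p_value < 0.001


class TestPressQ:
    def test_perfect_two_group_classification(self):
        counts = pd.DataFrame([[5, 0], [0, 5]], index=["a", "b"],
                              columns=["a", "b"])
        assert press_q(ClassificationTable.from_counts(counts)).q == \
            pytest.approx(10.0)

    def test_chance_level_is_zero(self):
        counts = pd.DataFrame([[5, 5], [5, 5]], index=["a", "b"],
                              columns=["a", "b"])
        assert press_q(ClassificationTable.from_counts(counts)).q == \
            pytest.approx(0.0)

    @given(st.integers(min_value=30, max_value=89))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_correct_count_above_chance(self, n_correct):
        """For fixed N, K, Q grows with the correct count above N/K."""
        def q_of(n):
            counts = pd.DataFrame(
                [[n, 90 - n, 0], [0, 0, 0], [0, 0, 0]],
                index=list("abc"), columns=list("abc"),
            )
            return press_q(ClassificationTable.from_counts(counts)).q

        assert q_of(n_correct + 1) >= q_of(n_correct)


class TestPotency:
    @pytest.mark.parametrize("loadings,expected", [
        ([0.74, -0.13], 0.33),   # eye diameter
        ([-0.03, 0.81], 0.27),   # second dorsal fin length
        ([-0.32, -0.60], 0.21),  # branchial length
    ])
    def test_published_loadings_and_shares(self, loadings, expected):
        pi = potency_index(np.array([loadings]), np.array([0.593, 0.407]))
        assert round(float(pi[0]), 2) == expected

    def test_single_full_share_function(self):
        assert potency_index(np.array([[1.0]]), np.array([1.0]))[0] == 1.0


class TestSizeIndependence:
    def test_orthogonal_scores_zero_r2(self):
        lengths = np.linspace(600, 1000, 20)
        scores = np.tile([1.0, -1.0], 10)[:, None]
        scores = scores - np.polyval(
            np.polyfit(lengths, scores[:, 0], 1), lengths
        )[:, None]
        res = score_size_independence(scores, lengths)
        assert res["r_squared"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(10)
        lengths = rng.uniform(600, 1000, 25)
        scores = 0.002 * lengths + rng.normal(0, 0.5, 25)
        res = score_size_independence(scores, lengths)
        r = np.corrcoef(lengths, scores)[0, 1]
        assert res["r_squared"].iloc[0] == pytest.approx(r**2, rel=1e-10)

    def test_adjusted_pipeline_scores_are_length_free(self):
        """Size-adjusted synthetic data: score-on-TL p > 0.05 in >= 90%."""
        from stockid import SizeAdjuster

        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            cfg = small_config(
                seed=3000 + seed, n_per_stratum=15,
                group_dev={"c1": [-0.06, 0.0, 0.06],
                           "c2": [0.06, -0.06, 0.0]},
            )
            table = generate_morphometrics(cfg)
            frame = table[["TL_mm", "c1", "c2", "c3"]]
            adj = SizeAdjuster().fit(frame, table["group"])
            adjusted = adj.transform(frame)
            model = fit_discriminant(adjusted, table["group"].to_numpy())
            res = score_size_independence(
                model.transform(adjusted), table["TL_mm"].to_numpy()
            )
            hits += (res["p"] > 0.05).all()
        assert hits >= 0.90 * n_runs
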