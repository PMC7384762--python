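"""Balancing, classifiers, SFS, LOO protocol and metrics."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from qusradiomics.classify import (
    ClassifierError,
    ClassifierSpec,
    _fld_loo_accuracy_batch,
    _knn_loo_accuracy_batch,
    _pairwise_sq,
    compute_metrics,
    fld_fit,
    loo_evaluate,
    roc_curve_points,
    sfs_select,
    train_classifier,
    undersample_majority,
)


def _two_gaussians(n1, n0, d=3, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(sep, 1, (n1, d)), rng.normal(0, 1, (n0, d))]
    y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
    return X, y


class TestUndersample:
    def test_35_24_to_24_24(self):
        X, y = _two_gaussians(35, 24)
        Xb, yb = undersample_majority(X, y, np.random.default_rng(0))
        assert (yb == 1).sum() == 24 and (yb == 0).sum() == 24

    def test_balanced_unchanged(self):
        X, y = _two_gaussians(20, 20)
        Xb, yb = undersample_majority(X, y, np.random.default_rng(0))
        assert Xb.shape == X.shape

    def test_seeded_determinism(self):
        X, y = _two_gaussians(35, 24)
        a, _ = undersample_majority(X, y, np.random.default_rng(7))
        b, _ = undersample_majority(X, y, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
        c, _ = undersample_majority(X, y, np.random.default_rng(8))
        assert not np.array_equal(a, c)

    def test_minority_always_kept(self):
        X, y = _two_gaussians(35, 24)
        _, yb = undersample_majority(X, y, np.random.default_rng(0))
        assert (yb == 0).sum() == 24


class TestFLD:
    def test_direction_matches_closed_form(self):
        X, y = _two_gaussians(20, 20, d=2, sep=1.5, seed=1)
        w, t = fld_fit(X, y, ridge=0.0)
        mu1 = X[y == 1].mean(0)
        mu0 = X[y == 0].mean(0)
        Xc = X - np.where(y[:, None] == 1, mu1, mu0)
        w_closed = np.linalg.solve(Xc.T @ Xc, mu1 - mu0)
        w_closed /= np.linalg.norm(w_closed)
        assert abs(abs(w @ w_closed) - 1.0) < 1e-10  # parallel unit vectors

    def test_direction_parallel_to_sklearn_lda(self):
        X, y = _two_gaussians(30, 30, d=3, sep=1.0, seed=2)
        w, _ = fld_fit(X, y, ridge=0.0)
        lda = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        v = lda.coef_.ravel()
        cos = abs(w @ v) / np.linalg.norm(v)
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_batch_loo_matches_naive_loop(self):
        X, y = _two_gaussians(12, 10, d=2, sep=0.8, seed=3)
        Xs = X[None]  # one candidate set
        batch_acc = _fld_loo_accuracy_batch(Xs, y)[0]
        correct = 0
        for j in range(len(y)):
            tr = np.ones(len(y), bool)
            tr[j] = False
            w, t = fld_fit(X[tr], y[tr])
            correct += int((X[j] @ w - t > 0) == (y[j] == 1))
        assert batch_acc == pytest.approx(correct / len(y))


class TestKNN:
    def test_batch_loo_matches_naive_loop(self):
        X, y = _two_gaussians(10, 9, d=3, sep=0.7, seed=4)
        D = _pairwise_sq(X).sum(axis=0)
        k = 3
        batch_acc = _knn_loo_accuracy_batch(D[None], y, k)[0]
        correct = 0
        for j in range(len(y)):
            d = D[j].copy()
            d[j] = np.inf
            nn = np.argsort(d)[:k]
            pred = int(y[nn].sum() * 2 > k)
            correct += pred == y[j]
        assert batch_acc == pytest.approx(correct / len(y))


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["FLD", "KNN", "SVM_RBF"])
    def test_separable_training_accuracy(self, kind):
        X, y = _two_gaussians(25, 25, sep=5.0, seed=5)
        model = train_classifier(ClassifierSpec(kind=kind), X, y, {"k": 3})
        scores, preds = model.decision_scores(X)
        assert (preds == y).mean() > 0.97
        assert np.all((scores > 0) == preds.astype(bool))

    def test_single_class_is_error(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ClassifierError):
            train_classifier(ClassifierSpec(kind="FLD"), X, np.ones(10, int))


class TestSFS:
    def test_single_candidate_is_chosen(self):
        X, y = _two_gaussians(12, 12, d=1, sep=1.0, seed=6)
        sel = sfs_select(ClassifierSpec(kind="FLD"), X, y)
        assert sel == [0]

    def test_informative_feature_found_first_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        n = 40
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = rng.normal(size=(n, 3))
        X[:, 1] += 2.0 * y  # only feature 1 carries signal
        spec = ClassifierSpec(kind="FLD")
        sel = sfs_select(spec, X, y)
        # exhaustive single-feature oracle
        accs = [_fld_loo_accuracy_batch(X[:, [j]][None], y)[0] for j in range(3)]
        assert sel[0] == int(np.argmax(accs)) == 1

    @pytest.mark.parametrize("kind", ["FLD", "KNN", "SVM_RBF"])
    def test_never_more_than_four_features(self, kind):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 20))
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        sel = sfs_select(ClassifierSpec(kind=kind), X, y, rng=rng)
        assert 1 <= len(sel) <= 4

    def test_deterministic_tie_break_by_feature_order(self):
        X, y = _two_gaussians(10, 10, d=2, seed=9)
        X[:, 1] = X[:, 0]  # identical features tie exactly
        sel = sfs_select(ClassifierSpec(kind="FLD"), X, y)
        assert sel[0] == 0


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 1, 0, 0, 1])
        m, _ = compute_metrics(y, y, np.array([0.9, 0.8, 0.1, 0.2, 0.7]))
        assert (m.Sn, m.Sp, m.Acc, m.F1, m.AUC) == (100.0, 100.0, 100.0, 1.0, 1.0)

    def test_confusion_matrix_hand_arithmetic(self):
        # TP=29, FN=6, TN=19, FP=5 -> Sn 82.9 %, Sp 79.2 %, Acc 81.4 %
        y_true = np.r_[np.ones(35, int), np.zeros(24, int)]
        y_pred = np.r_[np.ones(29, int), np.zeros(6, int), np.ones(5, int), np.zeros(19, int)]
        scores = y_pred + np.linspace(0, 0.1, 59)
        m, _ = compute_metrics(y_true, y_pred, scores)
        assert m.Sn == pytest.approx(100 * 29 / 35, abs=0.05)
        assert m.Sp == pytest.approx(100 * 19 / 24, abs=0.05)
        assert m.Acc == pytest.approx(100 * 48 / 59, abs=0.05)
        ppv = 29 / 34
        sn = 29 / 35
        assert m.F1 == pytest.approx(2 * sn * ppv / (sn + ppv), abs=1e-9)

    def test_auc_equals_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            scores = rng.normal(size=30)
            m, _ = compute_metrics(y, (scores > 0).astype(int), scores)
            pos = scores[y == 1]
            neg = scores[y == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]
            ).sum()
            assert m.AUC == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_score_reversal_flips_auc(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 40)
        scores = rng.normal(size=40) + y
        m1, _ = compute_metrics(y, y, scores)
        m2, _ = compute_metrics(y, y, -scores)
        assert m1.AUC + m2.AUC == pytest.approx(1.0, abs=1e-12)

    def test_accuracy_is_prevalence_weighted_combination(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        m, _ = compute_metrics(y, pred, rng.normal(size=50))
        prev = y.mean()
        assert m.Acc == pytest.approx(m.Sn * prev + m.Sp * (1 - prev), abs=1e-9)

    def test_roc_starts_and_ends_at_corners(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 20)
        fpr, tpr = roc_curve_points(y, rng.normal(size=20))
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestLOOEvaluate:
    def test_separable_cohort_is_recovered(self):
        X, y = _two_gaussians(18, 14, d=4, sep=5.0, seed=14)
        rep = loo_evaluate(ClassifierSpec(kind="FLD"), X, y, n_balance_iters=2, seed=0)
        assert rep.metrics.Acc > 95.0
        assert rep.metrics.AUC > 0.98

    def test_label_permutation_gives_chance_accuracy(self):
        rng = np.random.default_rng(15)
        X, y = _two_gaussians(16, 16, d=3, sep=2.0, seed=15)
        accs = []
        for seed in range(4):
            yp = rng.permutation(y)
            rep = loo_evaluate(ClassifierSpec(kind="FLD"), X, yp, n_balance_iters=1, seed=seed)
            accs.append(rep.metrics.Acc)
        assert 25.0 < np.mean(accs) < 75.0

    def test_averaging_over_iterations_reduces_variance(self):
        X, y = _two_gaussians(20, 14, d=3, sep=1.0, seed=16)

        def acc_sd(iters):
            accs = [
                loo_evaluate(
                    ClassifierSpec(kind="FLD"), X, y, n_balance_iters=iters, seed=s
                ).metrics.Acc
                for s in range(6)
            ]
            return np.std(accs)

        assert acc_sd(4) <= acc_sd(1) + 1e-9

    def test_selection_counts_and_report_shape(self):
        X, y = _two_gaussians(12, 10, d=5, sep=1.0, seed=17)
        rep = loo_evaluate(
            ClassifierSpec(kind="KNN"),
            X,
            y,
            n_balance_iters=1,
            seed=0,
            feature_names=[f"F{i}" for i in range(5)],
        )
        assert rep.n_iterations == 1  # K-NN runs unbalanced, single iteration
        assert sum(rep.selection_counts.values()) >= len(y)  # >= 1 feature per fold
        assert set(rep.selection_counts) <= {f"F{i}" for i in range(5)}
        y_true, y_pred, scores = rep.predictions[0]
        assert len(y_true) == len(y)

    def test_pooled_metrics_flag(self):
        X, y = _two_gaussians(12, 9, d=2, sep=2.0, seed=18)
        rep = loo_evaluate(
            ClassifierSpec(kind="FLD"), X, y, n_balance_iters=2, seed=0, pooled=True
        )
        assert rep.pooled_metrics is not None
        assert 0.0 <= rep.pooled_metrics.AUC <= 1.0

    def test_too_few_subjects_is_error(self):
        X, y = _two_gaussians(3, 2)
        with pytest.raises(ClassifierError):
            loo_evaluate(ClassifierSpec(kind="FLD"), X, y)
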