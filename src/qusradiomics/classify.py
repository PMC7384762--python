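"""Treatment-response classification protocol.

Implements the multivariate model-building chain: random under-sampling
of the majority class (FLD and SVM-RBF run balanced, K-NN unbalanced),
sequential forward selection (SFS) of 1-4 features in a wrapper
framework, hyperparameter tuning, and subject-level leave-one-out (LOO)
cross-validation in which standardization, feature selection and tuning
all happen strictly inside the training fold. Metrics (Sn, Sp, Acc,
AUC, F1) are averaged over balancing iterations.

The responder class ("R", encoded 1) is the positive class throughout.

Implementation notes: the SFS inner criterion is LOO-within-training
accuracy, evaluated in closed form (vectorized across candidate features
and held-out samples) for FLD and K-NN; for SVM-RBF, whose per-fit cost
is not amortizable, the inner criterion is a stratified 3-fold CV
accuracy computed on precomputed RBF kernels assembled incrementally
from per-feature squared-distance matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVC, _libsvm

_libsvm.set_verbosity_wrap(0)


class ClassifierError(ValueError):
    pass


@dataclass
class ClassifierSpec:
    """One classifier's protocol: kind, hyperparameter grids, balancing."""

    kind: Literal["FLD", "KNN", "SVM_RBF"]
    knn_k: int = 3
    knn_k_grid: tuple[int, ...] = (1, 3, 5, 7)
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)  # divided by n selected features
    max_features: int = 4
    sfs_inner_folds: int = 3  # SVM-RBF inner CV; FLD/K-NN use inner LOO
    ridge: float = 1e-6

    @property
    def balanced(self) -> bool:
        # protocol: FLD and SVM-RBF run on balanced data, K-NN unbalanced
        return self.kind in ("FLD", "SVM_RBF")


@dataclass
class Metrics:
    Sn: float  # %, sensitivity to the responder class
    Sp: float  # %
    Acc: float  # %
    AUC: float
    F1: float

    def as_dict(self) -> dict:
        return {"Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "AUC": self.AUC, "F1": self.F1}


@dataclass
class ClassifierReport:
    """LOO evaluation result averaged over balancing iterations."""

    kind: str
    metrics: Metrics
    per_iteration: list[Metrics]
    selection_counts: dict
    n_iterations: int
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr) of the first iteration
    predictions: list  # per iteration: (y_true, y_pred, scores)
    pooled_metrics: Metrics | None = None


# ---------------------------------------------------------------------------
# Balancing, standardization
# ---------------------------------------------------------------------------


def undersample_majority(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the majority class without replacement to the minority size."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ClassifierError("need exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    maj_idx = np.flatnonzero(y == majority)
    keep = rng.choice(maj_idx, size=counts.min(), replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(y == minority), keep]))
    return X[idx], y[idx]


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


# ---------------------------------------------------------------------------
# Fisher's linear discriminant
# ---------------------------------------------------------------------------


def fld_fit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> tuple[np.ndarray, float]:
    """Closed-form Fisher direction with midpoint threshold.

    Returns (w, t): the decision score of x is ``w @ x - t``, positive
    for the responder class. A singular within-class scatter is handled
    by a small ridge on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mu1 = X[y == 1].mean(axis=0)
    mu0 = X[y == 0].mean(axis=0)
    Xc = X - np.where(y[:, None] == 1, mu1[None, :], mu0[None, :])
    Sw = Xc.T @ Xc
    lam = ridge * max(np.trace(Sw) / X.shape[1], 1.0)
    w = np.linalg.solve(Sw + lam * np.eye(X.shape[1]), mu1 - mu0)
    # unit-norm direction: scores are signed distances to the boundary,
    # commensurable when pooling decision scores across LOO folds
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    t = float(w @ (mu1 + mu0) / 2.0)
    return w, t


def _fld_loo_accuracy_batch(Xs: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """LOO accuracy of FLD for a batch of candidate feature sets.

    ``Xs`` has shape (n_cand, n, d). Uses rank-one downdates of the
    class means and within-class scatter so every leave-one-out fit is a
    single batched solve.
    """
    n_cand, n, d = Xs.shape
    y = np.asarray(y)
    m1 = y == 1
    m0 = ~m1
    n1, n0 = int(m1.sum()), int(m0.sum())
    if n1 < 2 or n0 < 2:
        raise ClassifierError("class absent (or singleton) in training fold")
    mu1 = Xs[:, m1].mean(axis=1)  # (c, d)
    mu0 = Xs[:, m0].mean(axis=1)
    mu_own = np.where(m1[None, :, None], mu1[:, None, :], mu0[:, None, :])  # (c, n, d)
    Xc = Xs - mu_own
    Sw = np.einsum("cnd,cne->cde", Xc, Xc)  # (c, d, d)
    n_own = np.where(m1, n1, n0).astype(float)  # (n,)
    scale = n_own / (n_own - 1.0)
    # leave-one-out class means
    mu1_loo = np.where(
        m1[None, :, None],
        (n1 * mu1[:, None, :] - Xs) / (n1 - 1.0),
        mu1[:, None, :],
    )
    mu0_loo = np.where(
        m0[None, :, None],
        (n0 * mu0[:, None, :] - Xs) / (n0 - 1.0),
        mu0[:, None, :],
    )
    # leave-one-out scatter: Sw - (n_c/(n_c-1)) (x - mu_c)(x - mu_c)^T
    outer = Xc[:, :, :, None] * Xc[:, :, None, :]  # (c, n, d, d)
    Sw_loo = Sw[:, None] - scale[None, :, None, None] * outer
    tr = np.einsum("cndd->cn", Sw_loo) / d
    lam = ridge * np.maximum(tr, 1.0)
    A = Sw_loo + lam[:, :, None, None] * np.eye(d)[None, None]
    diff = mu1_loo - mu0_loo
    w = np.linalg.solve(A, diff[..., None])[..., 0]  # (c, n, d)
    score = np.einsum("cnd,cnd->cn", w, Xs - 0.5 * (mu1_loo + mu0_loo))
    pred = score > 0
    return (pred == m1[None, :]).mean(axis=1)


# ---------------------------------------------------------------------------
# K-nearest neighbours
# ---------------------------------------------------------------------------


def _knn_vote(dist_row: np.ndarray, y_train: np.ndarray, k: int) -> tuple[int, float]:
    """Majority vote among the k nearest with an inverse-rank score."""
    order = np.argsort(dist_row, kind="stable")[:k]
    votes = y_train[order]
    weights = 1.0 / np.arange(1, k + 1)
    score = float(np.sum(weights * (2 * votes - 1)) / weights.sum())
    pred = int(votes.sum() * 2 > k)
    return pred, score


def _knn_loo_accuracy_batch(D: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """LOO accuracy of K-NN from squared-distance matrices.

    ``D`` has shape (n_cand, n, n); the diagonal is excluded.
    """
    n = D.shape[-1]
    Dx = D + np.where(np.eye(n, dtype=bool), np.inf, 0.0)[None]
    k_eff = min(k, n - 1)
    idx = np.argpartition(Dx, k_eff - 1, axis=-1)[..., :k_eff]
    votes = np.asarray(y)[idx]  # (c, n, k)
    pred = votes.sum(axis=-1) * 2 > k_eff
    return (pred == (np.asarray(y) == 1)[None, :]).mean(axis=1)


# ---------------------------------------------------------------------------
# SVM-RBF via precomputed kernels
# ---------------------------------------------------------------------------


def _svm_cv_accuracy(
    D: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    C: float,
    gamma: float,
) -> float:
    """Stratified k-fold accuracy of an RBF SVM from a squared-distance matrix.

    Uses the low-level libsvm binding with a precomputed kernel: the SFS
    wrapper refits the SVM thousands of times per evaluation and the
    estimator-object overhead would dominate the runtime.
    """
    K = np.exp(-gamma * D)
    yf = np.asarray(y, dtype=np.float64)
    correct = 0
    total = 0
    for tr, te in folds:
        Ktr = np.ascontiguousarray(K[np.ix_(tr, tr)])
        model = _libsvm.fit(Ktr, yf[tr], svm_type=0, kernel="precomputed", C=C)
        Kte = np.ascontiguousarray(K[np.ix_(te, tr)])
        pred = _libsvm.predict(Kte, *model[:7], svm_type=0, kernel="precomputed")
        correct += int((pred == yf[te]).sum())
        total += te.size
    return correct / total


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = y.size
    test_sets: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            test_sets[i % n_folds].append(int(j))
    folds = []
    for te_list in test_sets:
        te = np.array(sorted(te_list))
        tr = np.setdiff1d(np.arange(n), te)
        folds.append((tr, te))
    return folds


# ---------------------------------------------------------------------------
# Sequential forward selection + tuning
# ---------------------------------------------------------------------------


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    """Per-feature squared-difference matrices, shape (p, n, n)."""
    cols = X.T[:, :, None]
    return (cols - np.swapaxes(cols, 1, 2)) ** 2


def _candidate_scores(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    selected: list[int],
    remaining: list[int],
    diffs2: np.ndarray,
    D_sel: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]] | None,
) -> np.ndarray:
    d_new = len(selected) + 1
    if spec.kind == "FLD":
        Xs = np.stack([X[:, selected + [c]] for c in remaining])
        return _fld_loo_accuracy_batch(Xs, y, spec.ridge)
    if spec.kind == "KNN":
        D = D_sel[None] + diffs2[remaining]
        return _knn_loo_accuracy_batch(D, y, spec.knn_k)
    # SVM-RBF: fixed mid-grid hyperparameters during the greedy search
    gamma = 1.0 / d_new
    out = np.empty(len(remaining))
    for i, c in enumerate(remaining):
        out[i] = _svm_cv_accuracy(D_sel + diffs2[c], y, folds, C=1.0, gamma=gamma)
    return out


def sfs_select(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    max_k: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Greedy forward selection maximizing inner-evaluation accuracy.

    Adds features one at a time (at least 1, at most ``max_k``); stops
    early when no candidate strictly improves the criterion. Ties break
    deterministically toward the lower (canonical) feature index.
    ``X`` must already be standardized on the training fold.
    """
    if max_k is None:
        max_k = spec.max_features
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if p < 1:
        raise ClassifierError("need at least one candidate feature")
    rng = rng or np.random.default_rng(0)
    diffs2 = _pairwise_sq(X) if spec.kind in ("KNN", "SVM_RBF") else None
    D_sel = np.zeros((n, n)) if diffs2 is not None else None
    folds = (
        _stratified_folds(y, min(spec.sfs_inner_folds, int(np.bincount(y).min())), rng)
        if spec.kind == "SVM_RBF"
        else None
    )
    selected: list[int] = []
    remaining = list(range(p))
    best = -np.inf
    while remaining and len(selected) < max_k:
        scores = _candidate_scores(spec, X, y, selected, remaining, diffs2, D_sel, folds)
        i_best = int(np.argmax(scores))  # argmax keeps first max -> lowest index
        if scores[i_best] <= best and selected:
            break
        best = float(scores[i_best])
        chosen = remaining.pop(i_best)
        selected.append(chosen)
        if D_sel is not None:
            D_sel = D_sel + diffs2[chosen]
    return selected


def _tune(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    selected: list[int],
    rng: np.random.Generator,
) -> dict:
    """Inner-evaluation hyperparameter tuning on the selected subset."""
    if spec.kind == "FLD":
        return {}
    Xsel = X[:, selected]
    if spec.kind == "KNN":
        D = _pairwise_sq(Xsel).sum(axis=0)
        best_k, best_acc = spec.knn_k, -np.inf
        for k in spec.knn_k_grid:
            if k >= y.size:
                continue
            acc = float(_knn_loo_accuracy_batch(D[None], y, k)[0])
            if acc > best_acc:
                best_k, best_acc = k, acc
        return {"k": best_k}
    D = _pairwise_sq(Xsel).sum(axis=0)
    folds = _stratified_folds(y, min(spec.sfs_inner_folds, int(np.bincount(y).min())), rng)
    best = None
    best_acc = -np.inf
    for C in spec.svm_c_grid:
        for g in spec.svm_gamma_grid:
            gamma = g / len(selected)
            acc = _svm_cv_accuracy(D, y, folds, C=C, gamma=gamma)
            if acc > best_acc:
                best, best_acc = {"C": C, "gamma": gamma}, acc
    return best


class _TrainedModel:
    """A fitted classifier exposing continuous decision scores."""

    def __init__(self, spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, hyper: dict):
        self.spec = spec
        self.hyper = hyper
        self.X = X
        self.y = y
        if spec.kind == "FLD":
            self.w, self.t = fld_fit(X, y, spec.ridge)
        elif spec.kind == "SVM_RBF":
            self.gamma = hyper.get("gamma", 1.0 / X.shape[1])
            D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
            K = np.exp(-self.gamma * D)
            self.clf = SVC(C=hyper.get("C", 1.0), kernel="precomputed")
            self.clf.fit(K, y)

    def decision_scores(self, Xtest: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (scores, predictions); positive score means responder."""
        Xtest = np.atleast_2d(Xtest)
        if self.spec.kind == "FLD":
            scores = Xtest @ self.w - self.t
            return scores, (scores > 0).astype(int)
        if self.spec.kind == "KNN":
            k = min(self.hyper.get("k", self.spec.knn_k), self.y.size)
            scores = np.empty(Xtest.shape[0])
            preds = np.empty(Xtest.shape[0], dtype=int)
            for i, x in enumerate(Xtest):
                dist = ((self.X - x) ** 2).sum(axis=1)
                preds[i], scores[i] = _knn_vote(dist, self.y, k)
            return scores, preds
        D = ((Xtest[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=-1)
        K = np.exp(-self.gamma * D)
        scores = self.clf.decision_function(K)
        preds = (scores > 0).astype(int)
        return scores, preds


def train_classifier(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, hyper: dict | None = None
) -> _TrainedModel:
    """Fit one classifier on (already standardized) training data."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ClassifierError("class absent from training fold")
    return _TrainedModel(spec, np.asarray(X, dtype=float), y, hyper or {})


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def roc_curve_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points by score thresholding (ties collapsed), from (0,0) to (1,1)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    ys = y_true[order]
    ss = scores[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    distinct = np.r_[np.diff(ss) != 0, True]
    P = max(int((y_true == 1).sum()), 1)
    N = max(int((y_true == 0).sum()), 1)
    tpr = np.r_[0.0, tps[distinct] / P]
    fpr = np.r_[0.0, fps[distinct] / N]
    return fpr, tpr


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
) -> tuple[Metrics, tuple[np.ndarray, np.ndarray]]:
    """Sn/Sp/Acc (percent), trapezoidal AUC and F1; responder = positive."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ClassifierError("empty evaluation")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / y_true.size
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * sn * ppv / (sn + ppv) if sn + ppv else 0.0
    fpr, tpr = roc_curve_points(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return Metrics(Sn=100 * sn, Sp=100 * sp, Acc=100 * acc, AUC=auc, F1=f1), (fpr, tpr)


# ---------------------------------------------------------------------------
# LOO evaluation
# ---------------------------------------------------------------------------


def loo_evaluate(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_balance_iters: int = 20,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    pooled: bool = False,
) -> ClassifierReport:
    """Subject-level leave-one-out evaluation of one classifier.

    For every balancing iteration (one, for the unbalanced K-NN
    protocol) and every held-out subject, standardization, SFS and
    hyperparameter tuning are rerun on the remaining subjects only; the
    held-out subject is then scored. Per-iteration metrics use the
    pooled LOO scores of that iteration and are averaged across
    iterations; ``pooled=True`` additionally reports metrics on the
    predictions pooled over all iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] < 6:
        raise ClassifierError("need at least 6 subjects")
    if not np.all(np.isfinite(X)):
        raise ClassifierError("features must be finite")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    iters = n_balance_iters if spec.balanced else 1
    per_iter: list[Metrics] = []
    predictions = []
    selection_counts: Counter = Counter()
    roc_first: tuple[np.ndarray, np.ndarray] | None = None
    n = X.shape[0]
    for _ in range(iters):
        yb = y
        y_pred = np.empty(n, dtype=int)
        scores = np.empty(n)
        for j in range(n):
            tr = np.ones(n, dtype=bool)
            tr[j] = False
            Xtr, ytr = X[tr], y[tr]
            if np.unique(ytr).size < 2:
                raise ClassifierError("class absent from training fold")
            if spec.balanced:
                # balance the training remainder only; every subject still
                # serves as a test sample
                Xtr, ytr = undersample_majority(Xtr, ytr, rng)
            mu, sd = _zscore_fit(Xtr)
            Xtr_z = (Xtr - mu) / sd
            xte_z = (X[j] - mu) / sd
            fold_rng = np.random.default_rng(rng.integers(2**31))
            sel = sfs_select(spec, Xtr_z, ytr, rng=fold_rng)
            hyper = _tune(spec, Xtr_z, ytr, sel, fold_rng)
            model = train_classifier(spec, Xtr_z[:, sel], ytr, hyper)
            s, p = model.decision_scores(xte_z[sel])
            scores[j] = s[0]
            y_pred[j] = p[0]
            selection_counts.update(feature_names[i] for i in sel)
        m, roc = compute_metrics(yb, y_pred, scores)
        if roc_first is None:
            roc_first = roc
        per_iter.append(m)
        predictions.append((yb.copy(), y_pred, scores))
    mean_metrics = Metrics(
        Sn=float(np.mean([m.Sn for m in per_iter])),
        Sp=float(np.mean([m.Sp for m in per_iter])),
        Acc=float(np.mean([m.Acc for m in per_iter])),
        AUC=float(np.mean([m.AUC for m in per_iter])),
        F1=float(np.mean([m.F1 for m in per_iter])),
    )
    pooled_metrics = None
    if pooled:
        yt = np.concatenate([p[0] for p in predictions])
        yp = np.concatenate([p[1] for p in predictions])
        sc = np.concatenate([p[2] for p in predictions])
        pooled_metrics, _ = compute_metrics(yt, yp, sc)
    return ClassifierReport(
        kind=spec.kind,
        metrics=mean_metrics,
        per_iteration=per_iter,
        selection_counts=dict(selection_counts),
        n_iterations=iters,
        roc=roc_first,
        predictions=predictions,
        pooled_metrics=pooled_metrics,
    )
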