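"""Five-classifier, cross-validated benign/malignant evaluation.

Classifiers: RBF-kernel soft-margin SVM, 5-nearest-neighbour vote,
pseudoquadratic discriminant analysis (per-class Gaussians with Moore–Penrose
pseudo-inverted covariances), and two small Levenberg–Marquardt-trained
neural networks — a pattern-recognition net (one-hot targets, argmax output)
and a fitting net (single output thresholded at 0.5).  The headline protocol
is stratified 10-fold cross-validation; per-fold confusion counts feed
accuracy, sensitivity, specificity and precision, averaged across folds.
The positive class is the malignant/sick label throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_NAMES",
    "FoldPlan",
    "ConfusionCounts",
    "EvaluationReport",
    "make_folds",
    "train_predict",
    "metrics",
    "cross_validate",
    "run_experiment",
    "holdout_evaluate",
]

CLASSIFIER_NAMES = ("svm", "knn", "lda", "patnet", "fitnet")
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


@dataclass(frozen=True)
class FoldPlan:
    """Partition of samples into k test folds (sizes differ by at most one)."""

    k: int
    assignments: np.ndarray  # sample index -> fold id
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def make_folds(labels, k: int = 10, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Deterministic (seeded) k-fold partition, stratified by default."""
    y = np.asarray(labels)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if k > counts.min():
            raise ValueError("k exceeds the smallest class count; cannot stratify")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    assign = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splits):
        assign[test] = f
    return FoldPlan(k=k, assignments=assign, seed=seed, stratified=stratified)


# ---------------------------------------------------------------------------
# individual classifiers
# ---------------------------------------------------------------------------

def _standardize(train: np.ndarray, test: np.ndarray):
    mu, sd = train.mean(0), train.std(0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def train_predict(name: str, X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, seed: int = 0) -> np.ndarray:
    """Fit one named classifier and predict test labels (0 = negative, 1 = positive).

    Features are standardized on training statistics only, so no test-set
    information leaks into the fit.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    Xtr, Xte = _standardize(X_train, X_test)

    if name == "svm":
        # sigma = median pairwise training distance; gamma = 1 / (2 sigma^2)
        d = cdist(Xtr, Xtr)
        sigma = np.median(d[np.triu_indices_from(d, k=1)])
        sigma = sigma if sigma > 0 else 1.0
        clf = SVC(C=1.0, kernel="rbf", gamma=1.0 / (2.0 * sigma ** 2))
        clf.fit(Xtr, y_train)
        return clf.predict(Xte).astype(int)
    if name == "knn":
        return _knn_predict(Xtr, y_train, Xte, k=5)
    if name == "lda":
        return _pseudoquadratic_predict(Xtr, y_train, Xte)
    if name == "patnet":
        net = _LMNet(n_outputs=2, seed=seed)
        net.fit(Xtr, np.eye(2)[y_train])
        return net.predict(Xte).argmax(axis=1)
    if name == "fitnet":
        net = _LMNet(n_outputs=1, seed=seed)
        net.fit(Xtr, y_train[:, None].astype(float))
        return (net.predict(Xte)[:, 0] > 0.5).astype(int)
    raise ValueError(f"unknown classifier {name!r}")


def _knn_predict(Xtr, ytr, Xte, k=5) -> np.ndarray:
    """Majority vote of the k nearest Euclidean neighbours, ties broken by
    total inverse distance of each class's voters."""
    nn = NearestNeighbors(n_neighbors=min(k, len(Xtr))).fit(Xtr)
    dist, idx = nn.kneighbors(Xte)
    out = np.empty(len(Xte), dtype=int)
    for i in range(len(Xte)):
        votes = ytr[idx[i]]
        classes, counts = np.unique(votes, return_counts=True)
        top = classes[counts == counts.max()]
        if top.size == 1:
            out[i] = top[0]
        else:
            w = {c: (1.0 / np.maximum(dist[i][votes == c], 1e-12)).sum() for c in top}
            out[i] = max(w, key=w.get)
    return out


def _pseudoquadratic_predict(Xtr, ytr, Xte) -> np.ndarray:
    """Quadratic discriminant with pseudo-inverted class covariances.

    Log-discriminant g_c(x) = -1/2 (x-mu_c)' S_c^+ (x-mu_c)
    - 1/2 log pdet(S_c) + log pi_c, where pdet is the product of non-null
    eigenvalues; robust to singular covariance on small folds.
    """
    classes = np.unique(ytr)
    scores = np.empty((len(Xte), classes.size))
    n = len(Xtr)
    for ci, c in enumerate(classes):
        Xc = Xtr[ytr == c]
        mu = Xc.mean(0)
        S = np.cov(Xc, rowvar=False, bias=False)
        S = np.atleast_2d(S)
        evals, evecs = np.linalg.eigh(S)
        tol = max(S.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 0.0)
        pos = evals > max(tol, 1e-12)
        inv = np.zeros_like(evals)
        inv[pos] = 1.0 / evals[pos]
        Sp = (evecs * inv) @ evecs.T
        logpdet = np.log(evals[pos]).sum() if pos.any() else 0.0
        d = Xte - mu
        mahal = np.einsum("ij,jk,ik->i", d, Sp, d)
        scores[:, ci] = -0.5 * mahal - 0.5 * logpdet + np.log(len(Xc) / n)
    return classes[np.argmax(scores, axis=1)]


class _LMNet:
    """One-hidden-layer (10 tanh units) network trained by Levenberg–Marquardt.

    Sum-squared-error objective; lambda starts at 1e-3 and adapts by factors
    of 10; at most ``max_iter`` accepted steps, returning best-so-far weights
    with a warning if the damping overflows before the gradient vanishes.
    """

    def __init__(self, n_hidden: int = 10, n_outputs: int = 1, max_iter: int = 200,
                 lam0: float = 1e-3, seed: int = 0):
        self.h, self.o, self.max_iter, self.lam0, self.seed = n_hidden, n_outputs, max_iter, lam0, seed

    def _unpack(self, w, d):
        n1 = self.h * (d + 1)
        W1 = w[:n1].reshape(self.h, d + 1)
        W2 = w[n1:].reshape(self.o, self.h + 1)
        return W1, W2

    def _forward(self, w, X1):
        W1, W2 = self._unpack(w, X1.shape[1] - 1)
        A = np.tanh(X1 @ W1.T)                       # (n, h)
        A1 = np.hstack([A, np.ones((len(A), 1))])
        return A, A1, A1 @ W2.T                      # out: (n, o)

    def fit(self, X: np.ndarray, T: np.ndarray) -> "_LMNet":
        n, d = X.shape
        X1 = np.hstack([X, np.ones((n, 1))])
        rng = np.random.default_rng(self.seed)
        w = rng.normal(0, 0.5, size=self.h * (d + 1) + self.o * (self.h + 1))
        lam = self.lam0
        _, _, out = self._forward(w, X1)
        sse = ((out - T) ** 2).sum()
        for _ in range(self.max_iter):
            A, A1, out = self._forward(w, X1)
            R = (out - T)                            # (n, o)
            J = self._jacobian(w, X1, A, A1)         # (n*o, p)
            g = J.T @ R.ravel()
            if np.linalg.norm(g, ord=np.inf) < 1e-7:
                break
            H = J.T @ J
            accepted = False
            while lam <= 1e10:
                try:
                    step = np.linalg.solve(H + lam * np.eye(H.shape[0]), -g)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                w_new = w + step
                _, _, out_new = self._forward(w_new, X1)
                sse_new = ((out_new - T) ** 2).sum()
                if sse_new < sse:
                    w, sse, lam = w_new, sse_new, max(lam / 10, 1e-12)
                    accepted = True
                    break
                lam *= 10
            if not accepted:
                warnings.warn("Levenberg-Marquardt stalled; keeping best-so-far weights",
                              RuntimeWarning)
                break
        self.w_, self.d_ = w, d
        return self

    def _jacobian(self, w, X1, A, A1):
        n, d1 = X1.shape
        W1, W2 = self._unpack(w, d1 - 1)
        p = w.size
        J = np.zeros((n * self.o, p))
        dA = 1.0 - A ** 2                            # (n, h)
        n1 = self.h * d1
        for k in range(self.o):
            rows = slice(k * n, (k + 1) * n)
            # d out_k / d W1[i, :] = W2[k, i] * (1 - A_i^2) * X1
            blk = (W2[k, :self.h][None, :] * dA)[:, :, None] * X1[:, None, :]
            J[rows, :n1] = blk.reshape(n, n1)
            J[rows, n1 + k * (self.h + 1): n1 + (k + 1) * (self.h + 1)] = A1
        # rows of J are ordered output-major; match residual raveling (sample-major)
        idx = np.arange(n * self.o).reshape(self.o, n).T.ravel()
        return J[idx]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X1 = np.hstack([X, np.ones((len(X), 1))])
        return self._forward(self.w_, X1)[2]


# ---------------------------------------------------------------------------
# metrics and experiment harness
# ---------------------------------------------------------------------------

def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and precision in percent.

    A zero denominator yields NaN with a warning (the caller excludes such
    folds from averages).
    """
    if counts.total < 1:
        raise ValueError("no tested samples")
    out = {}
    out["accuracy"] = 100.0 * (counts.tp + counts.tn) / counts.total
    for key, num, den in (
        ("sensitivity", counts.tp, counts.tp + counts.fn),
        ("specificity", counts.tn, counts.tn + counts.fp),
        ("precision", counts.tp, counts.tp + counts.fp),
    ):
        if den == 0:
            warnings.warn(f"{key} undefined (zero denominator)", RuntimeWarning)
            out[key] = float("nan")
        else:
            out[key] = 100.0 * num / den
    return out


@dataclass
class EvaluationReport:
    """Fold-wise confusion counts and derived metrics for each classifier."""

    fold_counts: dict[str, list[ConfusionCounts]]
    pooled: dict[str, ConfusionCounts] = field(init=False)
    fold_metrics: dict[str, pd.DataFrame] = field(init=False)

    def __post_init__(self):
        self.pooled = {}
        self.fold_metrics = {}
        for name, counts in self.fold_counts.items():
            pooled = counts[0]
            for c in counts[1:]:
                pooled = pooled + c
            self.pooled[name] = pooled
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self.fold_metrics[name] = pd.DataFrame([metrics(c) for c in counts])

    def mean_metrics(self, name: str) -> dict[str, float]:
        """Per-fold metrics averaged over folds (NaN folds excluded)."""
        df = self.fold_metrics[name]
        return {m: float(np.nanmean(df[m])) for m in METRIC_NAMES}

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name in self.fold_counts:
            mm = self.mean_metrics(name)
            sd = {f"{m}_sd": float(np.nanstd(self.fold_metrics[name][m])) for m in METRIC_NAMES}
            rows[name] = {**mm, **sd}
        return pd.DataFrame(rows).T


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def cross_validate(X: np.ndarray, y: np.ndarray, plan: FoldPlan,
                   classifiers=CLASSIFIER_NAMES, seed: int = 0) -> EvaluationReport:
    """Evaluate the classifier suite under the given fold plan.

    Every sample is tested exactly once per classifier; standardization is
    refit inside each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    fold_counts: dict[str, list[ConfusionCounts]] = {c: [] for c in classifiers}
    for f in range(plan.k):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        for name in classifiers:
            pred = train_predict(name, X[tr], y[tr], X[te], seed=seed)
            fold_counts[name].append(_confusion(y[te], pred))
    return EvaluationReport(fold_counts=fold_counts)


def run_experiment(table: pd.DataFrame, labels, subsets: dict[str, list[str]],
                   k: int = 10, seed: int = 0,
                   classifiers=CLASSIFIER_NAMES) -> dict[str, EvaluationReport]:
    """Full CV evaluation of each feature regime (e.g. texture-only,
    nonlinear-only, combined/selected) with the whole classifier suite."""
    y = encode_labels(labels)
    plan = make_folds(y, k=k, seed=seed)
    out = {}
    for regime, cols in subsets.items():
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"regime {regime!r} references unknown columns {missing}")
        out[regime] = cross_validate(table[cols].to_numpy(), y, plan,
                                     classifiers=classifiers, seed=seed)
    return out


def holdout_evaluate(table: pd.DataFrame, labels, cols: list[str],
                     test_size: float = 0.3, seed: int = 0,
                     classifiers=CLASSIFIER_NAMES) -> EvaluationReport:
    """Optional 70/30 holdout protocol (single split, stratified)."""
    y = encode_labels(labels)
    X = table[cols].to_numpy()
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=test_size,
                                          random_state=seed, stratify=y)
    counts = {}
    for name in classifiers:
        pred = train_predict(name, Xtr, ytr, Xte, seed=seed)
        counts[name] = [_confusion(yte, pred)]
    return EvaluationReport(fold_counts=counts)


def encode_labels(labels) -> np.ndarray:
    """Map labels to {0, 1} with the malignant/sick class positive."""
    y = np.asarray(labels)
    if y.dtype.kind in "iub":
        return y.astype(int)
    positive = {"malignant", "sick", "abnormal", "1", "positive"}
    return np.array([1 if str(v).lower() in positive else 0 for v in y])
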