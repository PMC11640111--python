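"""Kernel PCA feature extraction with a ridge-penalized linear classifier.

The pipeline: flatten each (T x C) sequence, compute the RBF kernel
K_ij = exp(-gamma * ||x_i - x_j||^2) on the training set, double-center
it, eigendecompose, and keep the components with the largest positive
eigenvalues.  Out-of-sample points are centered with the stored train
kernel means.  A one-vs-rest ridge regression on +/-1 targets over the
components then acts as the classifier; the L2 penalty shrinks the
weight put on uninformative components, which is where the dimensional
reduction effectively happens.

``KPCARidgeClassifier`` follows the model/results idiom: construct from
data, ``fit()`` returns a :class:`KPCARidgeResults` with predictions,
diagnostics and a ``summary()`` table.  The lower-level operations
(:func:`fit_kpca`, :func:`project_kpca`, :func:`fit_ridge`,
:func:`predict_kpca_ridge`) are exposed for direct use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

EIGENVALUE_TOL = 1e-10


class DegenerateKernelError(ValueError):
    """All training points identical: the centered kernel has no positive spectrum."""


@dataclass
class KernelModel:
    """Fitted RBF kernel PCA state."""

    gamma: float
    X_train: np.ndarray           # (n, d) flattened training vectors
    eigenvalues: np.ndarray       # (m,) descending, positive
    dual_coef: np.ndarray         # (n, m): projection = K_centered @ dual_coef
    train_components: np.ndarray  # (n, m) cached projection of the train set
    k_col_means: np.ndarray       # (n,) column means of the raw train kernel
    k_grand_mean: float
    n_components: int

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]


@dataclass
class RidgeModel:
    """One-vs-rest ridge weights over kernel components."""

    weights: np.ndarray      # (n_components, n_classes)
    intercepts: np.ndarray   # (n_classes,)
    classes: np.ndarray
    alpha: float


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim > 2:
        X = X.reshape(X.shape[0], -1)
    return X


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(A, B, metric="sqeuclidean"))


def fit_kpca(train_X: np.ndarray, gamma: float, n_components: int | None = None) -> KernelModel:
    """Fit RBF kernel PCA: kernel, double centering, eigendecomposition.

    Components with eigenvalue <= EIGENVALUE_TOL are dropped; the default
    component budget is min(n - 1, 256).  Component signs are fixed by
    making each component's largest-magnitude dual coefficient positive.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    X = _as_2d(train_X)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if n_components is None:
        n_components = min(n - 1, 256)

    K = rbf_kernel_matrix(X, X, gamma)
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand

    evals, evecs = eigh(Kc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > EIGENVALUE_TOL
    if not keep.any():
        raise DegenerateKernelError(
            "no positive eigenvalues: training points are all identical")
    evals, evecs = evals[keep][:n_components], evecs[:, keep][:, :n_components]

    # dual coefficients alpha_j = v_j / sqrt(lambda_j): projection of a
    # centered kernel row gives components on the principal-axis scale
    dual = evecs / np.sqrt(evals)[None, :]
    flip = np.sign(dual[np.abs(dual).argmax(axis=0), np.arange(dual.shape[1])])
    dual = dual * flip
    train_components = Kc @ dual
    return KernelModel(gamma=gamma, X_train=X, eigenvalues=evals, dual_coef=dual,
                       train_components=train_components, k_col_means=col_means,
                       k_grand_mean=grand, n_components=dual.shape[1])


def project_kpca(model: KernelModel, X: np.ndarray) -> np.ndarray:
    """Project new points using the stored train-kernel means for centering."""
    X = _as_2d(X)
    if X.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} != {model.X_train.shape[1]}")
    K = rbf_kernel_matrix(X, model.X_train, model.gamma)
    row_means = K.mean(axis=1)
    Kc = K - model.k_col_means[None, :] - row_means[:, None] + model.k_grand_mean
    return Kc @ model.dual_coef


def fit_ridge(components: np.ndarray, labels: np.ndarray, alpha: float = 1.0) -> RidgeModel:
    """One-vs-rest ridge least squares on +/-1 targets, closed form."""
    C = np.asarray(components, dtype=float)
    labels = np.asarray(labels)
    if C.shape[0] != len(labels):
        raise ValueError("components/labels length mismatch")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    Y = np.where(labels[:, None] == classes[None, :], 1.0, -1.0)
    # center so the intercept is unpenalized
    c_mean = C.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Cc, Yc = C - c_mean, Y - y_mean
    A = Cc.T @ Cc + alpha * np.eye(C.shape[1])
    W = np.linalg.solve(A, Cc.T @ Yc)
    b = y_mean - c_mean @ W
    return RidgeModel(weights=W, intercepts=b, classes=classes, alpha=alpha)


def ridge_scores(model: RidgeModel, components: np.ndarray) -> np.ndarray:
    return components @ model.weights + model.intercepts


def predict_kpca_ridge(kmodel: KernelModel, rmodel: RidgeModel, X: np.ndarray) -> np.ndarray:
    """Labels = argmax of per-class linear scores over projected components."""
    comps = project_kpca(kmodel, X)
    return rmodel.classes[ridge_scores(rmodel, comps).argmax(axis=1)]


def reduce_training_set(X: np.ndarray, labels: np.ndarray, factor: float,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random subset of size round(n * factor).

    Used to keep the O(n^3) eigendecomposition tractable on the large
    windowed variants; factor 1 is the identity.
    """
    if factor not in (1, 1.0, 0.25, 1 / 4, 1 / 16, 0.0625):
        raise ValueError("factor must be one of 1, 1/4, 1/16")
    labels = np.asarray(labels)
    if factor == 1 or factor == 1.0:
        return np.asarray(X), labels
    rng = np.random.default_rng(seed)
    n_target = int(round(len(labels) * factor))
    classes, counts = np.unique(labels, return_counts=True)
    # largest-remainder allocation: per-class quotas sum to n_target and
    # stay within one sample of exact proportionality
    exact = counts * factor
    quota = np.floor(exact).astype(int)
    remainder_order = np.argsort(-(exact - quota))
    for i in remainder_order[:n_target - quota.sum()]:
        quota[i] += 1
    keep: list[int] = []
    for cls, n_cls in zip(classes, quota):
        if n_cls == 0:
            warnings.warn(f"class {cls!r} emptied by reduction factor {factor}")
            continue
        idx = np.flatnonzero(labels == cls)
        keep.extend(rng.choice(idx, size=n_cls, replace=False))
    keep = sorted(keep)
    X = np.asarray(X)
    return X[keep], labels[keep]


class KPCARidgeClassifier:
    """Kernel-PCA + ridge state classifier (model object).

    Parameters
    ----------
    X, y
        Training sequences (n, T, C) or flat (n, d), and their labels.
    gamma
        RBF kernel width; the method's single main hyperparameter.
    alpha
        Ridge penalty strength (default 1.0).
    n_components
        Kernel components to retain; default min(n - 1, 256).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, gamma: float = 1e-3,
                 alpha: float = 1.0, n_components: int | None = None):
        self.X = _as_2d(np.asarray(X))
        self.y = np.asarray(y)
        self.gamma = gamma
        self.alpha = alpha
        self.n_components = n_components

    @classmethod
    def from_split(cls, split, **kwargs) -> "KPCARidgeClassifier":
        X, y = split.arrays("train")
        return cls(X, y, **kwargs)

    def fit(self) -> "KPCARidgeResults":
        kmodel = fit_kpca(self.X, self.gamma, self.n_components)
        rmodel = fit_ridge(kmodel.train_components, self.y, self.alpha)
        return KPCARidgeResults(model=self, kernel_model=kmodel, ridge_model=rmodel)


@dataclass
class KPCARidgeResults:
    model: KPCARidgeClassifier
    kernel_model: KernelModel
    ridge_model: RidgeModel
    _train_acc: float | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_kpca_ridge(self.kernel_model, self.ridge_model, X)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    @property
    def train_accuracy(self) -> float:
        if self._train_acc is None:
            pred = self.ridge_model.classes[
                ridge_scores(self.ridge_model, self.kernel_model.train_components).argmax(axis=1)]
            self._train_acc = float(np.mean(pred == self.model.y))
        return self._train_acc

    def summary(self) -> str:
        km = self.kernel_model
        lines = [
            "KPCA + Ridge classification results",
            "===================================",
            f"training samples      {km.n_train}",
            f"input dimension       {km.X_train.shape[1]}",
            f"gamma                 {km.gamma:g}",
            f"ridge alpha           {self.ridge_model.alpha:g}",
            f"components retained   {km.n_components}",
            f"top eigenvalue        {km.eigenvalues[0]:.6g}",
            f"classes               {len(self.ridge_model.classes)}",
            f"train accuracy        {self.train_accuracy:.4f}",
        ]
        return "\n".join(lines)


def gamma_grid_search(X_train, y_train, X_val, y_val,
                      gammas: np.ndarray | None = None, alpha: float = 1.0,
                      n_components: int | None = None) -> tuple[float, dict[float, float]]:
    """Select gamma on a log grid by validation accuracy."""
    if gammas is None:
        gammas = np.logspace(-6, 1, 8)
    scores: dict[float, float] = {}
    for g in gammas:
        res = KPCARidgeClassifier(X_train, y_train, gamma=float(g), alpha=alpha,
                                  n_components=n_components).fit()
        scores[float(g)] = res.score(X_val, y_val)
    best = max(scores, key=lambda g: (scores[g], -g))
    return best, scores
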