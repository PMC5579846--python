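"""The four classifiers of the evaluation pipeline.

* Gaussian maximum-a-posteriori decision making ("BDM"): one
  multivariate Gaussian fitted per class by maximum likelihood, test
  vectors assigned to the class maximizing log prior + log density.
* k-nearest-neighbor with Euclidean distance and majority vote (k = 7).
* RBF-kernel support vector machine, one-versus-one, with the pinned
  parameter pair C = 40, gamma = 0.2 (scikit-learn / libsvm backend).
* A single-hidden-layer perceptron with sigmoid activations trained by
  online back-propagation: hidden size round(0.5*(log2(2K) + 2K - 1))
  for K classes, weights initialized uniformly in [0, 0.2], learning
  rate 0.3, one-hot targets, and an adaptive stop when the last ten
  epoch errors fail to undercut the error eleven epochs back by 0.01.

All tie-breaks are deterministic: class order is the sorted order of the
training labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "GaussianClassModel",
    "bdm_fit",
    "bdm_predict",
    "knn_predict",
    "svm_train",
    "svm_predict",
    "hidden_neuron_count",
    "MlpModel",
    "ann_should_stop",
    "ann_train",
    "ann_predict",
    "fit_predict",
]


@dataclass
class ClassifierConfig:
    k: int = 7
    C: float = 40.0
    gamma: float = 0.2
    svm_fusion: str = "vote"  # 'vote' (libsvm pairwise voting) or 'confidence'
    learning_rate: float = 0.3
    init_low: float = 0.0
    init_high: float = 0.2
    stop_delta: float = 0.01
    stop_window: int = 10
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.svm_fusion not in ("vote", "confidence"):
            raise ValueError("svm_fusion must be 'vote' or 'confidence'")


# ---------------------------------------------------------------------------
# Gaussian MAP ("Bayesian decision making")
# ---------------------------------------------------------------------------

@dataclass
class GaussianClassModel:
    classes: np.ndarray
    means: np.ndarray       # (K, M)
    cholesky: List[np.ndarray]  # per-class lower Cholesky of the covariance
    log_priors: np.ndarray  # (K,)


def _regularized_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor of the covariance, ridging the diagonal by
    eps*(trace/M) with eps = 1e-6 (escalating tenfold) until positive
    definite."""
    m = cov.shape[0]
    base = max(np.trace(cov) / m, np.finfo(float).tiny)
    eps = 0.0
    for _ in range(30):
        try:
            return np.linalg.cholesky(cov + eps * base * np.eye(m))
        except np.linalg.LinAlgError:
            eps = 1e-6 if eps == 0.0 else eps * 10.0
    raise np.linalg.LinAlgError("covariance could not be regularized")


def bdm_fit(x: np.ndarray, y: np.ndarray) -> GaussianClassModel:
    """Maximum-likelihood class means and covariances; priors are the
    empirical class frequencies.  Each class needs >= 2 training rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    means, chols, priors = [], [], []
    for c in classes:
        xc = x[y == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training rows")
        means.append(xc.mean(axis=0))
        cov = np.cov(xc, rowvar=False, bias=True)  # ML estimate
        cov = np.atleast_2d(cov)
        chols.append(_regularized_cholesky(cov))
        priors.append(xc.shape[0] / x.shape[0])
    return GaussianClassModel(
        classes=classes,
        means=np.asarray(means),
        cholesky=chols,
        log_priors=np.log(np.asarray(priors)),
    )


def bdm_predict(model: GaussianClassModel, x: np.ndarray) -> np.ndarray:
    """Maximum-a-posteriori class of each test row (ties -> class order)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"test dimensionality {x.shape[1]} does not match model "
            f"{model.means.shape[1]}"
        )
    n, m = x.shape
    scores = np.empty((n, len(model.classes)))
    for i, (mu, chol, lp) in enumerate(
        zip(model.means, model.cholesky, model.log_priors)
    ):
        diff = (x - mu).T  # (M, n)
        sol = solve_triangular(chol, diff, lower=True)
        with np.errstate(over="ignore"):  # extreme outliers may reach inf
            maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        scores[:, i] = lp - 0.5 * (maha + logdet + m * math.log(2 * math.pi))
    # argmax breaks ties by the first (sorted) class
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# k-nearest-neighbor
# ---------------------------------------------------------------------------

def knn_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    k: int = 7,
) -> np.ndarray:
    """Majority vote over the k Euclidean-nearest training rows.

    Vote ties are broken by the smallest mean distance (within the k
    neighbors) among the tied classes, then by class order.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_y = np.asarray(train_y)
    n = train_x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds training size {n}")
    dists = cdist(test_x, train_x)
    # k smallest per row; full argsort keeps neighbor order deterministic
    nn = np.argsort(dists, axis=1, kind="stable")[:, :k]
    out = []
    for row, idx in zip(dists, nn):
        labels = train_y[idx]
        classes, counts = np.unique(labels, return_counts=True)
        top = counts.max()
        tied = classes[counts == top]
        if len(tied) == 1:
            out.append(tied[0])
            continue
        mean_d = [row[idx[labels == c]].mean() for c in tied]
        out.append(tied[int(np.argmin(mean_d))])  # argmin ties -> class order
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Support vector machine (RBF kernel, one-versus-one)
# ---------------------------------------------------------------------------

def svm_train(
    x: np.ndarray, y: np.ndarray, C: float = 40.0, gamma: float = 0.2
) -> SVC:
    """Train K(K-1)/2 pairwise RBF-kernel SVMs (libsvm backend)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training requires at least 2 classes")
    model = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    model.fit(np.asarray(x, dtype=float), y)
    return model


def svm_predict(model: SVC, x: np.ndarray, fusion: str = "vote") -> np.ndarray:
    """Multi-class decision from the pairwise machines.

    ``fusion='vote'`` is libsvm's pairwise max-vote (ties resolved by
    aggregated decision values, as in libsvm).  ``'confidence'`` assigns
    the class with the largest summed signed pairwise decision values.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if fusion == "vote":
        return model.predict(x)
    if fusion != "confidence":
        raise ValueError("fusion must be 'vote' or 'confidence'")
    dec = model.decision_function(x)  # (n, K*(K-1)/2), ovo
    classes = model.classes_
    k = len(classes)
    if k == 2:
        dec = dec.reshape(-1, 1)
    sums = np.zeros((x.shape[0], k))
    col = 0
    for i in range(k):
        for j in range(i + 1, k):
            sums[:, i] += dec[:, col]
            sums[:, j] -= dec[:, col]
            col += 1
    return classes[np.argmax(sums, axis=1)]


# ---------------------------------------------------------------------------
# Single-hidden-layer perceptron
# ---------------------------------------------------------------------------

def hidden_neuron_count(K: int) -> int:
    """Hidden-layer size for K classes: round-half-up of
    0.5 * (log2(2K) + 2K - 1)."""
    if K < 2:
        raise ValueError("need at least 2 classes")
    x = 0.5 * (math.log2(2 * K) + 2 * K - 1)
    return int(math.floor(x + 0.5))


@dataclass
class MlpModel:
    classes: np.ndarray
    w_hidden: np.ndarray  # (H, M+1), last column is the bias
    w_out: np.ndarray     # (K, H+1)
    epoch_errors: List[float] = field(default_factory=list)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def ann_should_stop(
    epoch_errors: Sequence[float], delta: float = 0.01, window: int = 10
) -> bool:
    """Adaptive stopping rule: stop at epoch i when
    min(E[i-window+1..i]) > E[i-window] - delta."""
    if len(epoch_errors) < window + 1:
        return False
    recent = epoch_errors[-window:]
    return min(recent) > epoch_errors[-window - 1] - delta


def ann_train(
    x: np.ndarray, y: np.ndarray, config: ClassifierConfig = ClassifierConfig()
) -> MlpModel:
    """Online back-propagation on squared error with one-hot targets.

    Samples are visited in a fresh seeded random order each epoch; the
    epoch error E_i is the average over training vectors of the sum of
    squared output errors, evaluated after the epoch's updates.
    Training stops by `ann_should_stop` or at ``config.max_epochs``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    K = len(classes)
    n, m = x.shape
    H = hidden_neuron_count(K)
    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(config.init_low, config.init_high, size=(H, m + 1))
    w2 = rng.uniform(config.init_low, config.init_high, size=(K, H + 1))
    targets = (y[:, None] == classes[None, :]).astype(float)  # (n, K)
    lr = config.learning_rate
    errors: List[float] = []
    for _epoch in range(config.max_epochs):
        for i in rng.permutation(n):
            xi = np.append(x[i], 1.0)            # (m+1,)
            h = _sigmoid(w1 @ xi)                # (H,)
            hb = np.append(h, 1.0)               # (H+1,)
            o = _sigmoid(w2 @ hb)                # (K,)
            d_out = (o - targets[i]) * o * (1.0 - o)
            d_hid = (w2[:, :H].T @ d_out) * h * (1.0 - h)
            w2 -= lr * np.outer(d_out, hb)
            w1 -= lr * np.outer(d_hid, xi)
        # epoch error over the whole training set
        hb_all = np.hstack([_sigmoid(x @ w1[:, :m].T + w1[:, m]), np.ones((n, 1))])
        o_all = _sigmoid(hb_all @ w2.T)
        e = float(np.mean(np.sum((o_all - targets) ** 2, axis=1)))
        if not np.isfinite(e):
            raise FloatingPointError(
                f"ANN training diverged at epoch {len(errors) + 1}"
            )
        errors.append(e)
        if ann_should_stop(errors, config.stop_delta, config.stop_window):
            break
    return MlpModel(classes=classes, w_hidden=w1, w_out=w2, epoch_errors=errors)


def ann_predict(model: MlpModel, x: np.ndarray) -> np.ndarray:
    """Class of the maximum output neuron (ties -> class order)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m = model.w_hidden.shape[1] - 1
    if x.shape[1] != m:
        raise ValueError(f"test dimensionality {x.shape[1]} does not match {m}")
    h = _sigmoid(x @ model.w_hidden[:, :m].T + model.w_hidden[:, m])
    o = _sigmoid(h @ model.w_out[:, :-1].T + model.w_out[:, -1])
    return model.classes[np.argmax(o, axis=1)]


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

CLASSIFIERS = ("bdm", "knn", "svm", "ann")


def fit_predict(
    name: str,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> np.ndarray:
    """Train the named classifier and label the test rows."""
    if name == "bdm":
        return bdm_predict(bdm_fit(train_x, train_y), test_x)
    if name == "knn":
        return knn_predict(train_x, train_y, test_x, k=config.k)
    if name == "svm":
        model = svm_train(train_x, train_y, C=config.C, gamma=config.gamma)
        return svm_predict(model, test_x, fusion=config.svm_fusion)
    if name == "ann":
        return ann_predict(ann_train(train_x, train_y, config), test_x)
    raise ValueError(f"unknown classifier {name!r}; allowed: {', '.join(CLASSIFIERS)}")
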