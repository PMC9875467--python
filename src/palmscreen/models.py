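"""The five compared classifiers over pallor features (and ROI thumbnails).

Four classical models consume the (mean a*, mean b*, mean G) feature
vector: Gaussian Naive Bayes, k-nearest neighbours (k=100, Euclidean,
uniform weights), a CART decision tree (min 10 instances per leaf, nodes
below 5 not split), and a sigmoid-kernel SVM (C=100, tolerance 0.1, at
most 100 iterations). The fifth is a miniature convnet over 32x32 ROI
thumbnails trained by SGD with L2 regularization 1e-4 for 10 epochs.

Every trained model exposes a single score contract: probability of the
anemic class in [0, 1], with label = anemic when score >= 0.5 (ties lean
anemic — in screening, the conservative direction).

Classical estimators are scikit-learn behind this module's surface; the
convnet is the package's own numpy implementation (palmscreen._cnn).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings

import numpy as np
from scipy.special import expit
from sklearn.ensemble import BaggingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from skimage.transform import resize

from .cohort import ANEMIC, NON_ANEMIC
from .segmentation import RoiCrop

logger = logging.getLogger(__name__)

MODEL_KINDS = ("naive_bayes", "knn", "decision_tree", "svm", "cnn")

#: Integer encoding used internally: anemic is the positive class.
LABEL_TO_INT = {NON_ANEMIC: 0, ANEMIC: 1}


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the five models (defaults as compared in the study).

    svm_epsilon is a regression-specific knob kept only for configuration
    fidelity; the classification solver does not use it.
    """

    knn_k: int = 100
    knn_metric: str = "euclidean"
    knn_weights: str = "uniform"
    tree_min_leaf: int = 10
    tree_min_split: int = 5
    tree_bagged: bool = False  # optional 100-tree bagged mode
    svm_kernel: str = "sigmoid"
    svm_c: float = 100.0
    svm_epsilon: float = 1.10  # unused by classification; fidelity only
    svm_tolerance: float = 0.1
    svm_max_iter: int = 100
    cnn_l2: float = 1e-4
    cnn_max_epochs: int = 10
    cnn_batch_size: int = 32
    cnn_lr: float = 0.01
    standardize: bool = True  # z-score features for SVM and k-NN
    include_std_a: bool = False
    seed: int = 0


@dataclasses.dataclass
class TrainedModel:
    """Opaque fitted model with a uniform anemic-probability score contract."""

    kind: str
    estimator: object
    scaler: StandardScaler | None
    n_features: int
    fingerprint: str
    converged: bool = True

    def score(self, x: np.ndarray) -> np.ndarray:
        """Probability of anemic, one value in [0, 1] per row/thumbnail."""
        x = np.asarray(x, dtype=np.float64)
        if self.kind == "cnn":
            if x.ndim == 3:
                x = x[np.newaxis]
            if x.ndim != 4 or x.shape[-1] != 3:
                raise ValueError(f"cnn expects (N, H, W, 3) thumbnails, got {x.shape}")
            return self.estimator.predict_proba(x)[:, 1]
        if x.ndim == 1:
            x = x[np.newaxis, :]
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(f"expected (N, {self.n_features}) features, got {x.shape}")
        if self.scaler is not None:
            x = self.scaler.transform(x)
        if self.kind == "svm":
            return expit(self.estimator.decision_function(x))
        proba = self.estimator.predict_proba(x)
        cls = list(self.estimator.classes_)
        return proba[:, cls.index(1)] if 1 in cls else np.zeros(len(x))

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, scores); score >= 0.5 maps to anemic."""
        s = self.score(x)
        labels = np.where(s >= 0.5, ANEMIC, NON_ANEMIC)
        return labels, s


def encode_labels(labels) -> np.ndarray:
    """Map anemic/non_anemic strings (or 0/1 ints) to ints, anemic = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(np.int64)
    return np.asarray([LABEL_TO_INT[l] for l in arr], dtype=np.int64)


def _fingerprint(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _check_two_classes(y: np.ndarray, kind: str):
    if len(np.unique(y)) < 2:
        raise ValueError(f"{kind}: training set must contain both classes")


def train_naive_bayes(x, labels, config: ClassifierConfig = ClassifierConfig()) -> TrainedModel:
    """Gaussian class-conditional Naive Bayes (log-domain Bayes rule)."""
    x, y = np.asarray(x, dtype=np.float64), encode_labels(labels)
    _check_two_classes(y, "naive_bayes")
    est = GaussianNB().fit(x, y)
    return TrainedModel("naive_bayes", est, None, x.shape[1], _fingerprint(x, y))


def train_knn(x, labels, config: ClassifierConfig = ClassifierConfig()) -> TrainedModel:
    """k-NN: score = anemic fraction among the k nearest (Euclidean, uniform).

    k is clamped to the training-set size when it exceeds it (logged).
    """
    x, y = np.asarray(x, dtype=np.float64), encode_labels(labels)
    k = min(config.knn_k, len(x))
    if k < config.knn_k:
        logger.warning("knn: k=%d exceeds n_train=%d, clamped", config.knn_k, len(x))
    scaler = StandardScaler().fit(x) if config.standardize else None
    xt = scaler.transform(x) if scaler is not None else x
    est = KNeighborsClassifier(
        n_neighbors=k, metric=config.knn_metric, weights=config.knn_weights
    ).fit(xt, y)
    return TrainedModel("knn", est, scaler, x.shape[1], _fingerprint(x, y))


def train_decision_tree(x, labels, config: ClassifierConfig = ClassifierConfig()) -> TrainedModel:
    """CART tree, greedy Gini splits, leaf score = anemic fraction at leaf."""
    x, y = np.asarray(x, dtype=np.float64), encode_labels(labels)
    _check_two_classes(y, "decision_tree")
    base = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=config.tree_min_leaf,
        min_samples_split=config.tree_min_split,
        random_state=config.seed,
    )
    est = (
        BaggingClassifier(base, n_estimators=100, random_state=config.seed)
        if config.tree_bagged
        else base
    )
    est.fit(x, y)
    return TrainedModel("decision_tree", est, None, x.shape[1], _fingerprint(x, y))


def train_svm(x, labels, config: ClassifierConfig = ClassifierConfig()) -> TrainedModel:
    """Sigmoid-kernel SVM, C=100, tol=0.1, iteration-capped dual solver.

    Features are standardized by default. Non-convergence within the cap is
    flagged (converged=False), not raised. Scores come from a logistic link
    on the decision value.
    """
    x, y = np.asarray(x, dtype=np.float64), encode_labels(labels)
    _check_two_classes(y, "svm")
    scaler = StandardScaler().fit(x) if config.standardize else None
    xt = scaler.transform(x) if scaler is not None else x
    est = SVC(
        kernel=config.svm_kernel,
        C=config.svm_c,
        tol=config.svm_tolerance,
        max_iter=config.svm_max_iter,
        gamma="scale",
        coef0=0.0,
        random_state=config.seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(xt, y)
        except ConvergenceWarning:
            converged = False
            logger.warning("svm: solver hit the %d-iteration cap", config.svm_max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(xt, y)
    return TrainedModel("svm", est, scaler, x.shape[1], _fingerprint(x, y), converged)


def train_cnn(thumbnails, labels, config: ClassifierConfig = ClassifierConfig()) -> TrainedModel:
    """Train the miniature convnet on 32x32 RGB thumbnails (seeded SGD)."""
    from ._cnn import TinyConvNet

    x = np.asarray(thumbnails, dtype=np.float64)
    y = encode_labels(labels)
    _check_two_classes(y, "cnn")
    net = TinyConvNet(input_hw=x.shape[1], seed=config.seed)
    net.fit(
        x,
        y,
        epochs=config.cnn_max_epochs,
        batch_size=config.cnn_batch_size,
        lr=config.cnn_lr,
        l2=config.cnn_l2,
    )
    return TrainedModel("cnn", net, None, x.shape[1], _fingerprint(x, y))


_TRAINERS = {
    "naive_bayes": train_naive_bayes,
    "knn": train_knn,
    "decision_tree": train_decision_tree,
    "svm": train_svm,
    "cnn": train_cnn,
}


def train(kind: str, x, labels, config: ClassifierConfig = ClassifierConfig()) -> TrainedModel:
    """Dispatch to the trainer for ``kind`` (one of MODEL_KINDS)."""
    if kind not in _TRAINERS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    return _TRAINERS[kind](x, labels, config)


def predict(model: TrainedModel, x) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) for a feature matrix or thumbnail batch."""
    return model.predict(x)


def make_thumbnail(crop: RoiCrop, size: int = 32) -> np.ndarray:
    """Downscale an ROI crop to a size x size x 3 uint8 thumbnail.

    Off-mask pixels are zeroed first so the background never contributes.
    """
    img = crop.pixels.astype(np.float64) / 255.0
    img[~crop.mask] = 0.0
    out = resize(img, (size, size, 3), anti_aliasing=True, mode="reflect")
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
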