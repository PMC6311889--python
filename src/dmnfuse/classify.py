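"""Group classification from mixing-coefficient features.

An RBF-kernel SVM is trained on the K-dimensional mixing coefficients, with
the penalty C and kernel width g chosen by cross-validated grid search on a
log2 grid of step 0.5, and a Platt sigmoid fitted to the training decision
values to produce probabilities.  The experiment repeats stratified
train/test splits (13 train / 5 test per class, 100 times by default),
refitting the fusion decomposition on each split's training subjects only,
and reports the mean accuracy, the ROC pooled over all test probabilities,
and its AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted


def log2_grid(start: float, stop: float, step: float = 0.5) -> np.ndarray:
    """2**start .. 2**stop inclusive, log2-spaced with the given step."""
    n = int(round((stop - start) / step))
    return 2.0 ** (start + step * np.arange(n + 1))


@dataclass
class SplitScheme:
    """Repeated stratified splitting: n_train/n_test per class, n_repeats times."""

    n_train_per_class: int = 13
    n_test_per_class: int = 5
    n_repeats: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train_per_class, self.n_test_per_class, self.n_repeats) < 1:
            raise ValueError("split sizes and n_repeats must be >= 1")


@dataclass
class ClassifierConfig:
    """Hyperparameter search space for the RBF SVM (log2 grids, step 0.5)."""

    C_grid: np.ndarray = field(default_factory=lambda: log2_grid(-5, 15))
    g_grid: np.ndarray = field(default_factory=lambda: log2_grid(-15, 3))
    cv_folds: int = 5

    def __post_init__(self) -> None:
        for name, grid in (("C_grid", self.C_grid), ("g_grid", self.g_grid)):
            grid = np.asarray(grid, dtype=float)
            if grid.size == 0:
                raise ValueError(f"{name} must be nonempty")
            if grid.size > 1:
                steps = np.diff(np.log2(grid))
                if not np.allclose(steps, 0.5, atol=1e-9):
                    raise ValueError(f"{name}: consecutive log2 steps must equal 0.5")
            setattr(self, name, grid)


def make_splits(
    labels: Sequence[str], scheme: SplitScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified splits; train/test disjoint within each split."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    need = scheme.n_train_per_class + scheme.n_test_per_class
    for c in classes:
        have = int((labels == c).sum())
        if have < need:
            raise ValueError(
                f"class {c!r} has {have} subjects; scheme needs "
                f"{scheme.n_train_per_class}+{scheme.n_test_per_class}={need}"
            )
    rng = np.random.default_rng(scheme.rng_seed)
    splits = []
    for _ in range(scheme.n_repeats):
        train, test = [], []
        for c in classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            train.append(idx[: scheme.n_train_per_class])
            test.append(idx[scheme.n_train_per_class : need])
        splits.append((np.sort(np.concatenate(train)), np.sort(np.concatenate(test))))
    return splits


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit p = 1/(1+exp(A f + B)) to {0,1} targets with Platt's smoothing."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * decision + b
        # stable log(1+exp(z)) and its pieces
        lse = np.logaddexp(0.0, z)
        return float(np.sum(t * lse + (1.0 - t) * (lse - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


class PlattRbfSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM with internal (C, g) grid search and Platt-calibrated output.

    The grid is scored by ``cv_folds``-fold cross-validated accuracy on the
    training set; ties resolve to the smallest C, then the smallest g.  The
    final SVM is refit on all training data and a sigmoid is fitted to its
    training decision values.  ``predict_proba`` returns the probability of
    ``classes_[1]``; ``predict`` thresholds it at 0.5.
    """

    def __init__(self, config: ClassifierConfig | None = None, random_state: int | None = 0):
        self.config = config
        self.random_state = random_state

    def fit(self, X, y) -> "PlattRbfSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes in training labels, got {len(self.classes_)}")
        cfg = self.config if self.config is not None else ClassifierConfig()
        y01 = (y == self.classes_[1]).astype(int)

        n_folds = min(cfg.cv_folds, int(np.bincount(y01).min()))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
        folds = list(skf.split(X, y01))

        best = (-np.inf, None, None)
        scores = np.empty((len(cfg.C_grid), len(cfg.g_grid)))
        for i, C in enumerate(cfg.C_grid):
            for j, g in enumerate(cfg.g_grid):
                correct = 0
                for tr, va in folds:
                    clf = SVC(C=C, gamma=g, kernel="rbf")
                    clf.fit(X[tr], y01[tr])
                    correct += int((clf.predict(X[va]) == y01[va]).sum())
                score = correct / len(y01)
                scores[i, j] = score
                if score > best[0] + 1e-12:  # strict: first max wins ties
                    best = (score, C, g)
        self.cv_scores_ = scores
        self.C_, self.gamma_ = float(best[1]), float(best[2])
        self.svm_ = SVC(C=self.C_, gamma=self.gamma_, kernel="rbf").fit(X, y01)
        f = self.svm_.decision_function(X)
        self.platt_a_, self.platt_b_ = _platt_fit(f, y01)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        f = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(self.platt_a_ * f + self.platt_b_))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > 0.5).astype(int)]


def train_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    config: ClassifierConfig | None = None,
    rng_seed: int | None = 0,
) -> PlattRbfSVC:
    return PlattRbfSVC(config=config, random_state=rng_seed).fit(features, labels)


def evaluate_split(
    model: PlattRbfSVC, test_features: np.ndarray, test_labels: Sequence[str]
) -> tuple[float, np.ndarray]:
    """Accuracy at probability threshold 0.5 plus per-subject P(class 2)."""
    test_features = np.asarray(test_features, dtype=float)
    check_is_fitted(model, "svm_")
    if test_features.shape[1] != model.svm_.shape_fit_[1]:
        raise ValueError(
            f"feature dimension {test_features.shape[1]} != "
            f"model dimension {model.svm_.shape_fit_[1]}"
        )
    prob2 = model.predict_proba(test_features)[:, 1]
    pred = model.classes_[(prob2 > 0.5).astype(int)]
    acc = float(np.mean(pred == np.asarray(test_labels)))
    return acc, prob2


def roc_and_auc(
    probabilities: np.ndarray, labels: Sequence, positive=None
) -> tuple[np.ndarray, float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    AUC is invariant to strictly monotone transforms of the probabilities.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; ROC undefined")
    pos = classes[-1] if positive is None else positive
    fpr, tpr, _ = roc_curve((labels == pos).astype(int), probabilities,
                            drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass
class ClassificationResult:
    """Aggregate of the repeated-split experiment for one seed combination."""

    per_split_accuracy: np.ndarray
    mean_accuracy: float
    roc_points: np.ndarray
    auc: float
    chosen_hyperparams: list[tuple[float, float]]
    pooled_probabilities: np.ndarray
    pooled_labels: np.ndarray


FusionRefit = Callable[[np.ndarray, np.ndarray, int], tuple[np.ndarray, np.ndarray]]


def run_repeated(
    labels: Sequence[str],
    scheme: SplitScheme,
    config: ClassifierConfig | None,
    fusion_refit: FusionRefit,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ClassificationResult:
    """Leakage-free repeated-split protocol.

    For every split, ``fusion_refit(train_idx, test_idx, split_index)`` must
    re-derive the decomposition from the training subjects only and return
    ``(train_features, test_features)``; the classifier is then trained on the
    training coefficients and evaluated on the projected test coefficients.
    No test subject influences its split's decomposition, normalization or
    hyperparameter choice.
    """
    labels = np.asarray(labels)
    if splits is None:
        splits = make_splits(labels, scheme)
    accs, hypers, probs, tlabs = [], [], [], []
    for s_idx, (tr, te) in enumerate(splits):
        try:
            feat_tr, feat_te = fusion_refit(tr, te, s_idx)
            model = PlattRbfSVC(config=config, random_state=scheme.rng_seed).fit(
                feat_tr, labels[tr]
            )
            acc, p2 = evaluate_split(model, feat_te, labels[te])
        except Exception as exc:
            raise RuntimeError(f"split {s_idx} failed: {exc}") from exc
        accs.append(acc)
        hypers.append((model.C_, model.gamma_))
        probs.append(p2)
        tlabs.append(labels[te])
    probs = np.concatenate(probs)
    tlabs = np.concatenate(tlabs)
    roc_pts, auc_val = roc_and_auc(probs, tlabs)
    accs = np.asarray(accs)
    return ClassificationResult(
        per_split_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        roc_points=roc_pts,
        auc=auc_val,
        chosen_hyperparams=hypers,
        pooled_probabilities=probs,
        pooled_labels=tlabs,
    )
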