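"""Partial least squares discriminant analysis (NIPALS PLS2), from scratch.

X is centred and (by default) scaled to unit variance; Y is a centred one-hot
class-indicator matrix.  Prediction uses the regression coefficients
``B = W (P^T W)^{-1} Q^T`` and assigns the argmax indicator column.
Leave-one-out cross-validation refits the full preprocessing + model inside
every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureMatrix",
    "PLSModel",
    "CVResult",
    "one_hot",
    "fit",
    "predict",
    "loo_misclassification",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class FeatureMatrix:
    X: np.ndarray  # (n_samples, n_features)
    feature_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("X contains undefined values; drop those features upstream")
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if X.shape[0] != len(self.labels) or X.shape[0] != len(self.sample_ids):
            raise ValueError("labels/sample_ids length mismatch")
        n_classes = len(set(self.labels))
        if X.shape[0] < n_classes:
            raise ValueError("need at least one sample per class")
        object.__setattr__(self, "X", X)

    @staticmethod
    def from_arrays(X, labels, feature_names=None, sample_ids=None) -> "FeatureMatrix":
        X = np.asarray(X, dtype=np.float64)
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
        if sample_ids is None:
            sample_ids = tuple(f"s{i}" for i in range(X.shape[0]))
        return FeatureMatrix(X, tuple(feature_names), tuple(sample_ids), tuple(labels))


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray  # ones when autoscaling is off
    y_mean: np.ndarray
    W: np.ndarray  # weights, (n_kept_features, A)
    P: np.ndarray  # X loadings
    Q: np.ndarray  # Y loadings, (n_classes, A)
    T: np.ndarray  # training scores, (n_samples, A)
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]  # kept (non-constant) features, in order
    dropped_features: tuple[str, ...]
    autoscaled: bool

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the processed X scale."""
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return R @ self.Q.T


@dataclass(frozen=True)
class CVResult:
    predicted: tuple[str, ...]
    true_labels: tuple[str, ...]
    misclassification_rate: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = true
    classes: tuple[str, ...]
    n_samples: int


def one_hot(labels) -> tuple[np.ndarray, tuple[str, ...]]:
    """Class-indicator matrix; column order is the sorted class list."""
    labels = list(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct class labels")
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def _preprocess(X: np.ndarray, feature_names, autoscale: bool):
    """Centre/scale after removing zero-variance features."""
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    kept = tuple(n for n, k in zip(feature_names, keep) if k)
    dropped = tuple(n for n, k in zip(feature_names, keep) if not k)
    Xk = X[:, keep]
    mean = Xk.mean(axis=0)
    scale = Xk.std(axis=0, ddof=0) if autoscale else np.ones(Xk.shape[1])
    return (Xk - mean) / scale, mean, scale, kept, dropped


def fit(fm: FeatureMatrix, n_components: int = 3, autoscale: bool = True) -> PLSModel:
    """NIPALS PLS2 against centred one-hot responses."""
    Y_raw, classes = one_hot(fm.labels)
    Xc, x_mean, x_scale, kept, dropped = _preprocess(
        fm.X, fm.feature_names, autoscale
    )
    if Xc.shape[1] == 0:
        raise ValueError("all features are constant")
    max_rank = min(Xc.shape[0] - 1, Xc.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds achievable rank {max_rank}"
        )
    y_mean = Y_raw.mean(axis=0)
    Y = Y_raw - y_mean

    n, p = Xc.shape
    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    T = np.zeros((n, A))

    Xd, Yd = Xc.copy(), Y.copy()
    for a in range(A):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if np.allclose(u, 0):
            raise ValueError(f"Y deflated to zero at component {a}: rank exhausted")
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"X deflated to zero at component {a}")
            w /= nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            u = Yd @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * (
                np.linalg.norm(t) + 1e-300
            ):
                break
            t_old = t
        p_a = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p_a)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q, t

    return PLSModel(
        n_components=A,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        W=W,
        P=P,
        Q=Q,
        T=T,
        classes=classes,
        feature_names=kept,
        dropped_features=dropped,
        autoscaled=autoscale,
    )


def _align_features(model: PLSModel, X_new: np.ndarray, feature_names) -> np.ndarray:
    names = tuple(feature_names)
    if names == model.feature_names:
        return X_new
    name_to_col = {n: i for i, n in enumerate(names)}
    missing = [n for n in model.feature_names if n not in name_to_col]
    if missing:
        extra = [n for n in names if n not in set(model.feature_names) | set(model.dropped_features)]
        raise ValueError(f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}")
    cols = [name_to_col[n] for n in model.feature_names]
    return X_new[:, cols]


def transform(model: PLSModel, X_new: np.ndarray, feature_names=None) -> np.ndarray:
    """Project new samples onto the model's score space."""
    if feature_names is not None:
        X_new = _align_features(model, np.asarray(X_new, float), feature_names)
    Xc = (np.asarray(X_new, float) - model.x_mean) / model.x_scale
    R = model.W @ np.linalg.inv(model.P.T @ model.W)
    return Xc @ R


def predict(
    model: PLSModel, X_new: np.ndarray, feature_names=None
) -> tuple[list[str], np.ndarray, list[int]]:
    """Predict classes; returns (labels, indicator predictions, tie indices)."""
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if feature_names is not None:
        X_new = _align_features(model, X_new, feature_names)
    elif X_new.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X_new.shape[1]}"
        )
    Xc = (X_new - model.x_mean) / model.x_scale
    Y_hat = Xc @ model.coefficients + model.y_mean
    ties: list[int] = []
    labels: list[str] = []
    for i, row in enumerate(Y_hat):
        best = np.flatnonzero(row == row.max())
        if len(best) > 1:
            ties.append(i)
        labels.append(model.classes[int(best[0])])
    return labels, Y_hat, ties


def loo_misclassification(
    fm: FeatureMatrix, n_components: int = 3, autoscale: bool = True
) -> CVResult:
    """Exact leave-one-out misclassification with per-fold refitting."""
    n = fm.X.shape[0]
    classes = tuple(sorted(set(fm.labels)))
    if n < len(classes) + 1:
        raise ValueError("need at least n_classes + 1 samples for LOO")
    for c in classes:
        if sum(1 for l in fm.labels if l == c) < 2:
            raise ValueError(
                f"class {c!r} has a single sample; a LOO fold would lose it entirely"
            )
    predicted: list[str] = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        fold = FeatureMatrix(
            fm.X[keep],
            fm.feature_names,
            tuple(fm.sample_ids[j] for j in keep),
            tuple(fm.labels[j] for j in keep),
        )
        model = fit(fold, n_components=n_components, autoscale=autoscale)
        # align by name: the fold may drop different constant features
        pred, _, _ = predict(model, fm.X[i : i + 1], feature_names=fm.feature_names)
        predicted.append(pred[0])

    n_wrong = sum(p != t for p, t in zip(predicted, fm.labels))
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(fm.labels, predicted):
        confusion[classes.index(t), classes.index(p)] += 1
    return CVResult(
        predicted=tuple(predicted),
        true_labels=tuple(fm.labels),
        misclassification_rate=n_wrong / n,
        confusion=confusion,
        classes=classes,
        n_samples=n,
    )
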