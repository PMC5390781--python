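"""Two-group Mahalanobis-distance classification of concentration features.

Each tissue state is summarised by the mean vector and covariance matrix of
its (c_w, c_c, c_p) feature vectors; a sample is assigned to the group with
the smaller squared Mahalanobis distance D2 = (x - mu)^T S^-1 (x - mu).  D2 is
invariant under any common invertible linear map of the feature space — in
particular under the global scaling induced by an unknown optical path length,
which is why fixing l = 1 in the unmixing does not degrade classification.

The positive class is "degraded" (disease detection): a false positive is a
normal sample labelled degraded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import FitError, SingularityError, TieWarning
from .unmixing import FeatureVector

__all__ = [
    "GroupModel",
    "ClassificationResult",
    "fit_group_model",
    "mahalanobis_d2",
    "classify",
    "classify_loo",
]

POSITIVE_LABEL = "degraded"
NEGATIVE_LABEL = "normal"


def as_feature_matrix(
    features: Sequence[FeatureVector] | np.ndarray,
) -> np.ndarray:
    """Coerce a list of FeatureVectors or an (n, 3) array to an (n, 3) float array."""
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("feature array must have shape (n, 3)")
        return X
    return np.array([fv.values for fv in features], dtype=float)


@dataclass
class GroupModel:
    """Gaussian summary of one group: mean, covariance (ddof=1) and size."""

    label: str
    mu: np.ndarray
    S: np.ndarray
    n: int
    _chol: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.mu.shape != (3,) or self.S.shape != (3, 3):
            raise ValueError("mu must be length 3 and S must be 3x3")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("S must be symmetric")
        if self.n < 4:
            raise FitError(f"group {self.label!r}: need n >= 4, got {self.n}")

    def cholesky(self) -> tuple:
        """Cached Cholesky factor of S; raises SingularityError if not PD."""
        if self._chol is None:
            try:
                self._chol = cho_factor(self.S, lower=True)
            except np.linalg.LinAlgError as exc:
                raise SingularityError(
                    f"group {self.label!r}: covariance not positive definite"
                ) from exc
        return self._chol


def fit_group_model(
    features: Sequence[FeatureVector] | np.ndarray,
    label: str,
    ridge: float = 0.0,
) -> GroupModel:
    """Sample mean and covariance of one group's feature vectors.

    ``ridge`` adds eps * I to the covariance; with ridge = 0 a singular
    covariance raises :class:`SingularityError` naming the deficient
    direction.
    """
    X = as_feature_matrix(features)
    n = X.shape[0]
    if n < 4:
        raise FitError(f"group {label!r}: need at least 4 samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"group {label!r}: non-finite feature values")
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    if ridge > 0:
        S = S + ridge * np.eye(3)
    else:
        w, v = np.linalg.eigh(S)
        if w.min() <= 1e-12 * max(w.max(), 1e-300):
            direction = v[:, int(np.argmin(w))]
            raise SingularityError(
                f"group {label!r}: covariance singular along direction "
                f"({direction[0]:+.4f}, {direction[1]:+.4f}, {direction[2]:+.4f}); "
                "add a ridge or more varied samples"
            )
    return GroupModel(label=label, mu=mu, S=S, n=n)


def mahalanobis_d2(
    x: FeatureVector | np.ndarray, g: GroupModel
) -> float:
    """Squared Mahalanobis distance of ``x`` to group ``g``.

    Computed through a Cholesky solve of S, never an explicit inverse.
    """
    v = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    d = v - g.mu
    return float(d @ cho_solve(g.cholesky(), d))


@dataclass
class ClassificationResult:
    """Per-sample predictions and (when truth is known) a confusion summary."""

    predicted: np.ndarray  # array of group labels
    d2: dict  # label -> array of squared distances
    false_pos: int | None = None  # normal classified as degraded
    false_neg: int | None = None  # degraded classified as normal
    total: int = 0

    @property
    def accuracy(self) -> float | None:
        if self.false_pos is None or self.false_neg is None:
            return None
        return 1.0 - (self.false_pos + self.false_neg) / self.total

    @property
    def false_pos_pct(self) -> float | None:
        return None if self.false_pos is None else 100.0 * self.false_pos / self.total

    @property
    def false_neg_pct(self) -> float | None:
        return None if self.false_neg is None else 100.0 * self.false_neg / self.total

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "false_pos": self.false_pos,
            "false_neg": self.false_neg,
            "false_pos_pct": self.false_pos_pct,
            "false_neg_pct": self.false_neg_pct,
            "accuracy": self.accuracy,
        }


def _predict(
    X: np.ndarray, models: Sequence[GroupModel]
) -> tuple[np.ndarray, dict]:
    d2 = {g.label: np.array([mahalanobis_d2(x, g) for x in X]) for g in models}
    labels = [g.label for g in models]
    D = np.column_stack([d2[lab] for lab in labels])
    ties = D[:, 0] == D[:, 1]
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} sample(s) equidistant from both groups; "
            f"ties broken toward {NEGATIVE_LABEL!r}",
            TieWarning,
            stacklevel=3,
        )
    pred = np.empty(len(X), dtype=object)
    for i in range(len(X)):
        if ties[i]:
            pred[i] = NEGATIVE_LABEL if NEGATIVE_LABEL in labels else labels[0]
        else:
            pred[i] = labels[int(np.argmin(D[i]))]
    return pred, d2


def _confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int]:
    truth = np.asarray(truth)
    fp = int(np.sum((truth == NEGATIVE_LABEL) & (pred == POSITIVE_LABEL)))
    fn = int(np.sum((truth == POSITIVE_LABEL) & (pred == NEGATIVE_LABEL)))
    return fp, fn


def classify(
    features: Sequence[FeatureVector] | np.ndarray,
    models: Sequence[GroupModel],
    truth: Sequence[str] | np.ndarray | None = None,
) -> ClassificationResult:
    """Assign each sample to the group with the smallest Mahalanobis distance.

    Exactly two group models are required.  Ties go to ``"normal"`` with a
    warning.  With ``truth`` labels, false positives (normal -> degraded) and
    false negatives (degraded -> normal) are counted over the grand total of
    classified samples.
    """
    if len(models) != 2:
        raise ValueError(f"exactly two group models required, got {len(models)}")
    X = as_feature_matrix(features)
    pred, d2 = _predict(X, models)
    result = ClassificationResult(predicted=pred, d2=d2, total=len(X))
    if truth is not None:
        if len(truth) != len(X):
            raise ValueError("truth labels must match the number of samples")
        result.false_pos, result.false_neg = _confusion(pred, np.asarray(truth))
    return result


def classify_loo(
    features: Sequence[FeatureVector] | np.ndarray,
    truth: Sequence[str] | np.ndarray,
    ridge: float = 0.0,
) -> ClassificationResult:
    """Leave-one-out protocol: each sample is scored against group models
    refitted without it, removing the optimistic bias of resubstitution."""
    X = as_feature_matrix(features)
    truth = np.asarray(truth)
    labels = sorted(set(truth.tolist()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    pred = np.empty(len(X), dtype=object)
    d2_store = {lab: np.empty(len(X)) for lab in labels}
    models_full = {
        lab: fit_group_model(X[truth == lab], lab, ridge=ridge) for lab in labels
    }
    for i in range(len(X)):
        own = truth[i]
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        held_out = fit_group_model(X[mask & (truth == own)], str(own), ridge=ridge)
        pair = [held_out if lab == own else models_full[lab] for lab in labels]
        p, d2 = _predict(X[i : i + 1], pair)
        pred[i] = p[0]
        for lab in labels:
            d2_store[lab][i] = d2[lab][0]
    result = ClassificationResult(predicted=pred, d2=d2_store, total=len(X))
    result.false_pos, result.false_neg = _confusion(pred, truth)
    return result
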