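"""Sample-weighted linear discriminant classification and
instance-weighted RBF-SVM with one-vs-one multiclass voting.

The weighted LDC generalizes classical LDA: class means, the pooled
within-class covariance and the class priors are all estimated under
per-class sample weights ``w_{k,i}``.  With one-hot weights it reduces
exactly to classical LDA; doubling a sample's weight is exactly
equivalent to duplicating the sample (the pooled-covariance denominator
is total weight minus the number of classes).

The SVM side wraps libsvm binary machines (via scikit-learn) per class
pair, where sample ``i`` carries an effective penalty ``C * w_i``;
multiclass labels come from one-vs-one majority voting with ties
resolved to the lowest class index in the fixed order (C, F, LRNC).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from plaqseg.constants import CLASS_NAMES
from plaqseg.errors import ValidationError

__all__ = [
    "LDCModel",
    "SVMModel",
    "fit_ldc",
    "predict_ldc",
    "fit_svm",
    "predict_svm",
]

logger = logging.getLogger(__name__)


@dataclass
class LDCModel:
    """Fitted weighted linear discriminant classifier."""

    classes: tuple[str, ...]
    means: np.ndarray  # (K, d)
    covariance: np.ndarray  # (d, d) pooled within-class
    priors: np.ndarray  # (K,)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "plaqseg-ldc",
                "version": 1,
                "classes": list(self.classes),
                "means": self.means.tolist(),
                "covariance": self.covariance.tolist(),
                "priors": self.priors.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LDCModel":
        obj = json.loads(text)
        if obj.get("format") != "plaqseg-ldc":
            raise ValidationError("not a serialized LDC model")
        return cls(
            classes=tuple(obj["classes"]),
            means=np.asarray(obj["means"], dtype=float),
            covariance=np.asarray(obj["covariance"], dtype=float),
            priors=np.asarray(obj["priors"], dtype=float),
        )


@dataclass
class SVMModel:
    """One-vs-one instance-weighted RBF-SVM ensemble."""

    classes: tuple[str, ...]
    C: float
    gamma: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    pair_models: list[tuple[int, int, SVC]] = field(default_factory=list)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_sd


def fit_ldc(
    X: np.ndarray,
    weights: np.ndarray,
    classes: tuple[str, ...] = CLASS_NAMES,
) -> LDCModel:
    """Fit the weighted LDC from features ``X`` (n, d) and per-class
    sample weights ``weights`` (n, K).

    ``mu_k`` is the ``w_k``-weighted mean, the pooled covariance is the
    weighted within-class scatter over (total weight - K), and priors
    are the normalized per-class weight totals.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(weights, dtype=float)
    if X.ndim != 2 or W.ndim != 2 or len(X) != len(W):
        raise ValidationError("X and weights must be 2D with matching rows")
    if W.shape[1] != len(classes):
        raise ValidationError("weights must have one column per class")
    if np.any(W < 0):
        raise ValidationError("weights must be non-negative")
    K = len(classes)
    d = X.shape[1]
    totals = W.sum(axis=0)
    if np.any(totals <= 0):
        bad = [classes[k] for k in np.flatnonzero(totals <= 0)]
        raise ValidationError(f"zero total weight for classes {bad}")

    means = (W.T @ X) / totals[:, None]
    scatter = np.zeros((d, d))
    for k in range(K):
        delta = X - means[k]
        scatter += (W[:, k][:, None] * delta).T @ delta
    denom = totals.sum() - K
    if denom <= 0:
        denom = totals.sum()
    cov = scatter / denom
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(cov) / d
        if ridge <= 0:  # all-zero within-class scatter
            ridge = 1e-12 * max(1.0, float(np.abs(means).max()) ** 2)
        logger.warning("singular pooled covariance; adding ridge %.3e", ridge)
        cov = cov + ridge * np.eye(d)
    priors = totals / totals.sum()
    return LDCModel(classes=tuple(classes), means=means, covariance=cov, priors=priors)


def predict_ldc(model: LDCModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities and argmax labels under the Gaussian
    shared-covariance Bayes rule; posterior rows sum to 1, ties resolve
    to the lowest class index."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.means.shape[1]:
        raise ValidationError(
            f"feature dimension {X.shape} does not match model ({model.means.shape[1]})"
        )
    try:
        L = np.linalg.cholesky(model.covariance)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("model covariance is not positive definite") from exc
    # log N(x; mu_k, Sigma) + log pi_k up to a shared constant
    scores = np.empty((len(X), len(model.classes)))
    for k, mu in enumerate(model.means):
        sol = np.linalg.solve(L, (X - mu).T)
        maha = np.einsum("ij,ij->j", sol, sol)
        scores[:, k] = -0.5 * maha + np.log(model.priors[k])
    scores -= scores.max(axis=1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.asarray(model.classes)[np.argmax(post, axis=1)]
    return post, labels


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    C: float = 1.0,
    gamma: float = 0.1,
    classes: tuple[str, ...] = CLASS_NAMES,
) -> SVMModel:
    """Fit one-vs-one instance-weighted RBF-SVMs.

    Features are standardized to zero mean / unit SD using the training
    statistics; sample ``i`` of a pair enters with effective penalty
    ``C * w_i`` (zero-weight samples are dropped from the pair).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if C <= 0 or gamma <= 0:
        raise ValidationError("C and gamma must be positive")
    if sample_weight is None:
        sample_weight = np.ones(len(X))
    w = np.asarray(sample_weight, dtype=float)
    if len(w) != len(X) or len(y) != len(X):
        raise ValidationError("X, y and sample_weight must have matching length")

    active = w > 0  # scaler from contributing samples only, so that
    mean = X[active].mean(axis=0)  # zero weight is exactly removal
    sd = X[active].std(axis=0)
    sd[sd == 0] = 1.0
    model = SVMModel(
        classes=tuple(classes), C=C, gamma=gamma, scaler_mean=mean, scaler_sd=sd
    )
    Xs = model.standardize(X)
    present = [c for c in classes if np.any((y == c) & (w > 0))]
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            ci, cj = classes[i], classes[j]
            sel = ((y == ci) | (y == cj)) & (w > 0)
            yb = np.where(y[sel] == ci, -1, 1)
            if ci not in present or cj not in present:
                raise ValidationError(f"pair ({ci}, {cj}) has an empty class")
            svc = SVC(kernel="rbf", C=C, gamma=gamma)
            svc.fit(Xs[sel], yb, sample_weight=w[sel])
            model.pair_models.append((i, j, svc))
    return model


def pairwise_decision_values(model: SVMModel, X: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Decision-function values f(x) of every pairwise machine (negative
    favours the lower-index class of the pair)."""
    Xs = model.standardize(X)
    return {(i, j): svc.decision_function(Xs) for i, j, svc in model.pair_models}


def predict_svm(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """One-vs-one majority-vote labels; each pairwise decision is
    thresholded at 0, vote ties resolve to the lowest class index."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.scaler_mean.shape[0]:
        raise ValidationError("feature dimension does not match model")
    votes = np.zeros((len(X), len(model.classes)), dtype=int)
    for (i, j), f in pairwise_decision_values(model, X).items():
        votes[f <= 0, i] += 1  # f == 0 goes to the lower class index
        votes[f > 0, j] += 1
    return np.asarray(model.classes)[np.argmax(votes, axis=1)]
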