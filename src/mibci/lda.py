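"""Gaussian discriminant analysis with a shared covariance (linear case).

The discriminant for class k is

    delta_k(x) = -1/2 log|Sigma| - 1/2 (x - mu_k)' Sigma^{-1} (x - mu_k) + log pi_k

with mu_k the class sample means, Sigma the pooled within-class covariance
(optionally shrunk toward its diagonal) and pi_k empirical class
frequencies.  Because Sigma is shared, pairwise decision boundaries
delta_k = delta_l are affine in x.  Time plays no role: the classifier
consumes one flattened feature vector per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["LDAParams", "fit_lda", "discriminant", "predict_lda"]


@dataclass
class LDAParams:
    classes: tuple[str, ...]
    means: np.ndarray       # (K, d)
    covariance: np.ndarray  # (d, d), shared, regularized
    priors: np.ndarray      # (K,)
    shrinkage: float

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "shrinkage": self.shrinkage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAParams":
        return cls(
            classes=tuple(d["classes"]),
            means=np.asarray(d["means"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            shrinkage=float(d["shrinkage"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "LDAParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_lda(features: np.ndarray, labels, shrinkage: float = 0.0) -> LDAParams:
    """Fit class means, empirical priors and a pooled, shrunk covariance.

    Sigma = (1 - lambda) * Sigma_pooled + lambda * D, where D is the
    diagonal of Sigma_pooled with zero entries floored (so that even a
    zero-spread degenerate fit is invertible for lambda > 0).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D trials x features array")
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError(f"shrinkage must lie in [0, 1], got {shrinkage}")
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes in training data, found {classes}")

    n, d = X.shape
    means = np.empty((len(classes), d))
    priors = np.empty(len(classes))
    scatter = np.zeros((d, d))
    for k, c in enumerate(classes):
        Xk = X[y == c]
        if Xk.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training trials")
        means[k] = Xk.mean(axis=0)
        priors[k] = Xk.shape[0] / n
        centered = Xk - means[k]
        scatter += centered.T @ centered
    pooled = scatter / (n - len(classes))

    diag = np.diag(pooled).copy()
    floor = 1e-12 * diag.max() if diag.max() > 0 else 1.0
    diag = np.maximum(diag, floor)
    cov = (1.0 - shrinkage) * pooled + shrinkage * np.diag(diag)

    return LDAParams(classes=classes, means=means, covariance=cov, priors=priors, shrinkage=shrinkage)


def _cholesky(params: LDAParams) -> np.ndarray:
    try:
        return linalg.cholesky(params.covariance, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular shared covariance; refit with shrinkage > 0"
        ) from exc


def discriminant(params: LDAParams, x: np.ndarray) -> np.ndarray:
    """Per-class scores delta_k(x); accepts one vector (d,) or a batch (n, d)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.means.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match fitted dimension {params.means.shape[1]}"
        )
    L = _cholesky(params)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))

    scores = np.empty((X.shape[0], len(params.classes)))
    for k in range(len(params.classes)):
        diff = (X - params.means[k]).T  # (d, n)
        z = linalg.solve_triangular(L, diff, lower=True)
        maha = np.sum(z * z, axis=0)
        scores[:, k] = -0.5 * logdet - 0.5 * maha + np.log(params.priors[k])
    return scores[0] if single else scores


def predict_lda(params: LDAParams, x: np.ndarray):
    """Argmax of the discriminant; ties resolve to the lexicographically
    first class label (class order is sorted at fit time)."""
    scores = discriminant(params, x)
    if scores.ndim == 1:
        return params.classes[int(np.argmax(scores))]
    idx = np.argmax(scores, axis=1)
    return np.array([params.classes[i] for i in idx])
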