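"""Linear-chain hidden conditional random field (HCRF).

A discriminative sequence classifier: each output label y owns a disjoint
set H_y of m hidden states, and the conditional probability of a label
given an observation sequence x_1..x_T is

    p(y | x) = (1/Z) sum_{h in H_y^T} prod_t exp( sum_k theta_k f_k(h_t, h_{t-1}, x_t) )

with Z summing the same quantity over every label's hidden-path set.
Feature functions are first order: per-state observation weights (one
weight per hidden state and input feature), per-state biases, and
transition weights between ordered pairs of hidden states within a
label's set (cross-label transitions are structurally excluded by the
disjointness restriction).  Training maximizes the L2-penalized
conditional log-likelihood with L-BFGS; all path sums run in log space
via the forward recursion (never a linear-space partition function), and
gradients come from forward-backward marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .features import FeatureSequence

__all__ = [
    "HCRFParams",
    "label_log_score",
    "posterior",
    "nll_and_gradient",
    "train_hcrf",
    "predict_hcrf",
]


@dataclass
class HCRFParams:
    """Fitted HCRF state: label set, hidden states per label, flat theta.

    ``n_states`` is either one integer (the same m for every label) or a
    tuple giving each label's hidden-set size; the sets are disjoint by
    construction, so no cross-label transition weight exists.
    """

    classes: tuple[str, ...]
    n_states: int | tuple[int, ...]
    n_features: int
    theta: np.ndarray
    reg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size != n_parameters(self.state_counts, self.n_features):
            raise ValueError("theta length inconsistent with classes/states/features")

    @property
    def state_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_states, int):
            return (self.n_states,) * len(self.classes)
        counts = tuple(self.n_states)
        if len(counts) != len(self.classes):
            raise ValueError("n_states tuple must give one count per label")
        return counts

    def _offset(self, label_idx: int) -> int:
        d = self.n_features
        return sum(m * d + m + m * m for m in self.state_counts[:label_idx])

    def unpack(self, label_idx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W (m,d), b (m,), T (m,m)) for one label's hidden-state set."""
        m, d = self.state_counts[label_idx], self.n_features
        off = self._offset(label_idx)
        W = self.theta[off : off + m * d].reshape(m, d)
        b = self.theta[off + m * d : off + m * d + m]
        T = self.theta[off + m * d + m : off + m * d + m + m * m].reshape(m, m)
        return W, b, T

    def to_dict(self) -> dict:
        out = {
            "classes": list(self.classes),
            "n_states": self.n_states,
            "n_features": self.n_features,
            "reg": self.reg,
            "seed": self.seed,
            "weights": {},
        }
        for yi, y in enumerate(self.classes):
            W, b, T = self.unpack(yi)
            out["weights"][y] = {
                "observation": W.tolist(),
                "bias": b.tolist(),
                "transition": T.tolist(),
            }
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "HCRFParams":
        classes = tuple(d["classes"])
        raw_m = d["n_states"]
        n_states = int(raw_m) if isinstance(raw_m, int) else tuple(raw_m)
        nf = int(d["n_features"])
        pieces = []
        for y in classes:
            w = d["weights"][y]
            pieces += [
                np.asarray(w["observation"], dtype=float).reshape(-1),
                np.asarray(w["bias"], dtype=float),
                np.asarray(w["transition"], dtype=float).reshape(-1),
            ]
        return cls(classes=classes, n_states=n_states, n_features=nf,
                   theta=np.concatenate(pieces), reg=float(d["reg"]), seed=int(d["seed"]))

    @classmethod
    def load(cls, path) -> "HCRFParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def n_parameters(state_counts, d: int, n_labels: int | None = None) -> int:
    """Length of the flat weight vector.

    ``state_counts`` is a per-label tuple, or a single int combined with
    ``n_labels``."""
    if isinstance(state_counts, int):
        state_counts = (state_counts,) * (n_labels if n_labels is not None else 1)
    return sum(m * d + m + m * m for m in state_counts)


def _seq_values(seq) -> np.ndarray:
    if isinstance(seq, FeatureSequence):
        return seq.values
    return np.asarray(seq, dtype=float)


def _forward(U: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Log-space forward pass.  U: (n, Tlen, m) node potentials; returns
    alpha (n, Tlen, m) with alpha[:, t, s] = log-sum over partial paths."""
    n, Tlen, m = U.shape
    alpha = np.empty_like(U)
    alpha[:, 0] = U[:, 0]
    for t in range(1, Tlen):
        # logsumexp over previous state s': alpha[t-1, s'] + T[s', s]
        alpha[:, t] = logsumexp(alpha[:, t - 1, :, None] + T[None], axis=1) + U[:, t]
    return alpha


def _backward(U: np.ndarray, T: np.ndarray) -> np.ndarray:
    n, Tlen, m = U.shape
    beta = np.zeros_like(U)
    for t in range(Tlen - 2, -1, -1):
        beta[:, t] = logsumexp(T[None] + (U[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
    return beta


def _label_scores(params: HCRFParams, X: np.ndarray) -> np.ndarray:
    """(n, K) log of the unnormalized per-label path sums."""
    scores = np.empty((X.shape[0], len(params.classes)))
    for yi in range(len(params.classes)):
        W, b, T = params.unpack(yi)
        U = X @ W.T + b  # (n, Tlen, m)
        alpha = _forward(U, T)
        scores[:, yi] = logsumexp(alpha[:, -1], axis=1)
    return scores


def label_log_score(params: HCRFParams, seq, y: str) -> float:
    """log sum over hidden paths in H_y of the exponentiated path score."""
    X = _seq_values(seq)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("sequence must be a nonempty windows x features array")
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"sequence has {X.shape[1]} features, model trained with {params.n_features}"
        )
    yi = params.classes.index(y)
    return float(_label_scores(params, X[None])[0, yi])


def posterior(params: HCRFParams, seq) -> np.ndarray:
    """p(y|x) for each label in ``params.classes`` order; sums to 1."""
    X = _seq_values(seq)
    if X.shape[-1] != params.n_features:
        raise ValueError(
            f"sequence has {X.shape[-1]} features, model trained with {params.n_features}"
        )
    scores = _label_scores(params, X[None])[0]
    logZ = logsumexp(scores)
    return np.exp(scores - logZ)


def predict_hcrf(params: HCRFParams, seq) -> str:
    """Argmax posterior label; ties resolve to the first label in order."""
    return params.classes[int(np.argmax(posterior(params, seq)))]


def _encode_training_set(sequences, labels=None) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if labels is None:
        labels = [s.label for s in sequences]
    X = np.stack([_seq_values(s) for s in sequences])
    classes = tuple(sorted(set(labels)))
    y_idx = np.array([classes.index(l) for l in labels])
    return X, y_idx, classes


def nll_and_gradient(
    theta: np.ndarray,
    X: np.ndarray,
    y_idx: np.ndarray,
    classes: tuple[str, ...],
    n_states: int,
    reg: float,
) -> tuple[float, np.ndarray]:
    """Negative conditional log-likelihood and its gradient over theta.

    Objective: -sum_i log p(y_i | x_i) + (reg/2) ||theta||^2.  The gradient
    is the model expectation of each feature count (weighted by p(y|x))
    minus its expectation clamped to the observed label, from
    forward-backward marginals, plus reg * theta.
    """
    n, Tlen, d = X.shape
    K = len(classes)
    params = HCRFParams(classes=classes, n_states=n_states, n_features=d, theta=theta, reg=reg)

    scores = np.empty((n, K))
    per_label = []
    for yi in range(K):
        W, b, T = params.unpack(yi)
        U = X @ W.T + b
        alpha = _forward(U, T)
        beta = _backward(U, T)
        s = logsumexp(alpha[:, -1], axis=1)
        scores[:, yi] = s
        per_label.append((U, T, alpha, beta, s))

    logZ = logsumexp(scores, axis=1)
    if not np.all(np.isfinite(logZ)):
        bad = int(np.flatnonzero(~np.isfinite(logZ))[0])
        raise FloatingPointError(f"non-finite HCRF objective at trial {bad}")
    post = np.exp(scores - logZ[:, None])  # (n, K)
    nll = float(np.sum(logZ - scores[np.arange(n), y_idx])) + 0.5 * reg * float(theta @ theta)

    grad = reg * theta.copy()
    for yi in range(K):
        m = params.state_counts[yi]
        U, T, alpha, beta, s = per_label[yi]
        # model-minus-clamped coefficient per trial
        c = post[:, yi] - (y_idx == yi).astype(float)  # (n,)
        gamma = np.exp(alpha + beta - s[:, None, None])  # (n, Tlen, m) state marginals
        cg = c[:, None, None] * gamma
        dW = np.einsum("ntm,ntd->md", cg, X)
        db = cg.sum(axis=(0, 1))
        dT = np.zeros((m, m))
        for t in range(1, Tlen):
            xi = np.exp(
                alpha[:, t - 1, :, None]
                + T[None]
                + (U[:, t] + beta[:, t])[:, None, :]
                - s[:, None, None]
            )
            dT += np.einsum("n,nab->ab", c, xi)
        off = params._offset(yi)
        grad[off : off + m * d] += dW.reshape(-1)
        grad[off + m * d : off + m * d + m] += db
        grad[off + m * d + m : off + m * d + m + m * m] += dT.reshape(-1)
    return nll, grad


def train_hcrf(
    sequences,
    labels=None,
    n_states: int = 3,
    reg: float = 1.0,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 500,
    gtol: float = 1e-5,
) -> HCRFParams:
    """Maximum conditional likelihood training with seeded random restarts.

    ``sequences`` is a list of FeatureSequence (labels taken from them) or
    of (T, d) arrays with ``labels`` given separately.  All sequences must
    share a window count.  Initial weights are drawn i.i.d. N(0, 0.1^2);
    among restarts the lowest final objective wins.  The hidden-path
    likelihood is non-convex, hence the restarts.
    """
    X, y_idx, classes = _encode_training_set(sequences, labels)
    if len(classes) < 2:
        raise ValueError(f"need at least 2 labels in training data, found {classes}")
    n, Tlen, d = X.shape
    n_par = n_parameters(n_states, d, n_labels=len(classes))
    rng = np.random.default_rng(seed)

    best = None
    failures = []
    for r in range(max(1, restarts)):
        theta0 = 0.1 * rng.standard_normal(n_par)
        res = optimize.minimize(
            nll_and_gradient,
            theta0,
            args=(X, y_idx, classes, n_states, reg),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-10},
        )
        if not np.all(np.isfinite(res.x)):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"HCRF training failed on all restarts: {failures}")
    return HCRFParams(
        classes=classes, n_states=n_states, n_features=d, theta=best.x, reg=reg, seed=seed
    )
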