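"""Hidden CRF: forward recursion vs path enumeration, gradients, training."""

import itertools

import numpy as np
import pytest

from mibci.hcrf import (
    HCRFParams,
    label_log_score,
    n_parameters,
    nll_and_gradient,
    posterior,
    predict_hcrf,
    train_hcrf,
)


def brute_force_log_score(params: HCRFParams, X: np.ndarray, label_idx: int) -> float:
    """Enumerate every hidden path in the label's disjoint state set."""
    W, b, T = params.unpack(label_idx)
    U = X @ W.T + b
    total = -np.inf
    m = params.state_counts[label_idx]
    for path in itertools.product(range(m), repeat=X.shape[0]):
        s = U[0, path[0]]
        for t in range(1, len(path)):
            s += T[path[t - 1], path[t]] + U[t, path[t]]
        total = np.logaddexp(total, s)
    return total


def random_params(rng, m, d, classes=("a", "b"), scale=1.0):
    theta = scale * rng.standard_normal(n_parameters(m, d, n_labels=len(classes)))
    return HCRFParams(classes=classes, n_states=m, n_features=d, theta=theta)


@pytest.mark.parametrize("T", [1, 2, 3, 4])
@pytest.mark.parametrize("m", [1, 2, 3])
def test_forward_equals_path_enumeration(T, m, rng):
    d = 3
    for _ in range(5):
        params = random_params(rng, m, d)
        X = rng.standard_normal((T, d))
        for yi, y in enumerate(params.classes):
            assert label_log_score(params, X, y) == pytest.approx(
                brute_force_log_score(params, X, yi), abs=1e-10
            )


def test_zero_weights_score_counts_paths(rng):
    m, T, d = 3, 4, 2
    params = HCRFParams(
        classes=("a", "b"), n_states=m, n_features=d,
        theta=np.zeros(n_parameters(m, d, n_labels=2)),
    )
    X = rng.standard_normal((T, d))
    for y in params.classes:
        assert label_log_score(params, X, y) == pytest.approx(T * np.log(m))
    np.testing.assert_allclose(posterior(params, X), [0.5, 0.5])


def test_unequal_state_sets_posterior_is_path_ratio():
    """theta = 0, |H_a| = 1, |H_b| = 2, T = 2: path counts 1 vs 4."""
    params = HCRFParams(
        classes=("a", "b"), n_states=(1, 2), n_features=2,
        theta=np.zeros(n_parameters((1, 2), 2)),
    )
    X = np.zeros((2, 2))
    np.testing.assert_allclose(posterior(params, X), [0.2, 0.8], atol=1e-12)


def test_single_window_reduces_to_state_logsumexp(rng):
    params = random_params(rng, 2, 3)
    X = rng.standard_normal((1, 3))
    W, b, _ = params.unpack(0)
    expected = np.logaddexp.reduce(X[0] @ W.T + b)
    assert label_log_score(params, X, "a") == pytest.approx(expected, abs=1e-12)


def test_posterior_normalizes_and_survives_large_weights(rng):
    params = random_params(rng, 3, 4, scale=1e3)
    X = rng.standard_normal((6, 4))
    p = posterior(params, X)
    assert np.all(np.isfinite(p))
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_feature_mismatch_rejected(rng):
    params = random_params(rng, 2, 3)
    with pytest.raises(ValueError, match="features"):
        label_log_score(params, rng.standard_normal((4, 5)), "a")


def test_gradient_matches_finite_differences(rng):
    for trial in range(20):
        m = int(rng.integers(1, 4))
        T = int(rng.integers(1, 5))
        d = int(rng.integers(1, 4))
        n = int(rng.integers(2, 6))
        reg = float(rng.uniform(0, 2))
        theta = rng.standard_normal(n_parameters(m, d, n_labels=2))
        X = rng.standard_normal((n, T, d))
        y = rng.integers(0, 2, size=n)
        y[0], y[1] = 0, 1  # both labels present
        _, g = nll_and_gradient(theta, X, y, ("a", "b"), m, reg)
        eps = 1e-5
        for i in rng.choice(theta.size, size=min(6, theta.size), replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (
                nll_and_gradient(tp, X, y, ("a", "b"), m, reg)[0]
                - nll_and_gradient(tm, X, y, ("a", "b"), m, reg)[0]
            ) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-5)


def test_zero_weights_objective_is_n_log2(rng):
    n, T, d, m = 8, 3, 2, 2
    theta = np.zeros(n_parameters(m, d, n_labels=2))
    X = rng.standard_normal((n, T, d))
    y = np.array([0, 1] * 4)
    nll, _ = nll_and_gradient(theta, X, y, ("a", "b"), m, 0.0)
    assert nll == pytest.approx(n * np.log(2))


def make_separable_sequences(rng, n_per_class, T=4, d=2, gap=2.0):
    seqs = [rng.standard_normal((T, d)) + [gap, 0] for _ in range(n_per_class)]
    seqs += [rng.standard_normal((T, d)) + [-gap, 0] for _ in range(n_per_class)]
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    return seqs, labels


def test_training_fits_separable_sequences(rng):
    seqs, labels = make_separable_sequences(rng, 20)
    params = train_hcrf(seqs, labels, n_states=2, reg=1.0, seed=0, restarts=2, max_iter=200)
    preds = [predict_hcrf(params, s) for s in seqs]
    assert np.mean(np.array(preds) == np.array(labels)) == 1.0


def test_training_deterministic_under_seed(rng):
    seqs, labels = make_separable_sequences(rng, 10)
    a = train_hcrf(seqs, labels, n_states=2, reg=1.0, seed=5, restarts=2, max_iter=100)
    b = train_hcrf(seqs, labels, n_states=2, reg=1.0, seed=5, restarts=2, max_iter=100)
    np.testing.assert_array_equal(a.theta, b.theta)


def test_strong_regularization_shrinks_weights(rng):
    seqs, labels = make_separable_sequences(rng, 10)
    params = train_hcrf(seqs, labels, n_states=2, reg=1e6, seed=0, restarts=1, max_iter=200)
    assert np.max(np.abs(params.theta)) < 1e-3


def test_uniform_posterior_ties_to_first_label():
    params = HCRFParams(
        classes=("a", "b"), n_states=2, n_features=2,
        theta=np.zeros(n_parameters(2, 2, n_labels=2)),
    )
    assert predict_hcrf(params, np.zeros((3, 2))) == "a"


def test_hcrf_uses_temporal_order_lda_cannot(rng):
    """Class identity carried only by window order: ascending vs descending
    ramps with identical per-trial value multisets once shuffled.  The HCRF
    sees ordered sequences; LDA sees flattened shuffled windows and must
    drop to chance while the HCRF stays far above."""
    from mibci.lda import fit_lda, predict_lda

    def make(n, ascending):
        out = []
        for _ in range(n):
            ramp = np.linspace(-1.5, 1.5, 4) + 0.3 * rng.standard_normal(4)
            if not ascending:
                ramp = ramp[::-1]
            out.append(ramp[:, None] * np.ones((1, 2)))
        return out

    n_train, n_test = 60, 80
    train = make(n_train, True) + make(n_train, False)
    test = make(n_test, True) + make(n_test, False)
    y_train = np.array(["up"] * n_train + ["down"] * n_train)
    y_test = np.array(["up"] * n_test + ["down"] * n_test)

    params = train_hcrf(list(train), list(y_train), n_states=2, reg=0.1, seed=0,
                        restarts=2, max_iter=200)
    hcrf_acc = np.mean([predict_hcrf(params, s) for s in test] == y_test)

    def shuffle_windows(seqs):
        return np.stack([s[rng.permutation(s.shape[0])].reshape(-1) for s in seqs])

    lda_params = fit_lda(shuffle_windows(train), y_train, shrinkage=0.01)
    lda_acc = np.mean(predict_lda(lda_params, shuffle_windows(test)) == y_test)

    # 95% binomial CI half-widths at n=160 are ~0.08; demand clear separation
    assert hcrf_acc > 0.9
    assert abs(lda_acc - 0.5) < 0.15
    assert hcrf_acc - lda_acc > 0.2


def test_hcrf_serialization_round_trip(tmp_path, rng):
    seqs, labels = make_separable_sequences(rng, 6)
    params = train_hcrf(seqs, labels, n_states=2, reg=1.0, seed=1, restarts=1, max_iter=50)
    path = tmp_path / "hcrf.json"
    params.save(path)
    back = HCRFParams.load(path)
    np.testing.assert_allclose(back.theta, params.theta)
    x = rng.standard_normal((4, 2))
    np.testing.assert_allclose(posterior(back, x), posterior(params, x))
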