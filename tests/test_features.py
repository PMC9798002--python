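"""Sliding windows, band powers, scaling, and interaction measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mibci.features import (
    BandDefinition,
    DEFAULT_BANDS,
    PowerScaler,
    WindowSpec,
    band_power,
    extract_features,
    features_to_frame,
    flatten_for_static,
    jaccard_distance,
    jaccard_index,
    pearson,
    slide_windows,
)
from mibci.synth import SignalModel, Trial, feedback_paradigm, generate_session

FS = 250.0


# ---------------------------------------------------------------- windows

def brute_force_windows(n, k, step):
    return [(i, i + k) for i in range(0, n) if i + k <= n and i % step == 0]


@pytest.mark.parametrize(
    "n,window_s,slide_s,expected",
    [
        (750, 2.0, 0.5, [(0, 500), (125, 625), (250, 750)]),
        (500, 2.0, 2.0, [(0, 500)]),  # whole-segment case
        (750, 0.5, 0.5, [(i * 125, (i + 1) * 125) for i in range(6)]),
    ],
)
def test_slide_windows_examples(n, window_s, slide_s, expected):
    assert slide_windows(n, WindowSpec(window_s, slide_s), FS) == expected


@given(
    n=st.integers(2, 50),
    k=st.integers(2, 50),
    step=st.integers(1, 10),
)
def test_window_count_matches_enumeration(n, k, step):
    spec = WindowSpec(k / FS, step / FS)
    if k > n:
        with pytest.raises(ValueError):
            slide_windows(n, spec, FS)
        return
    ranges = slide_windows(n, spec, FS)
    assert ranges == brute_force_windows(n, k, step)
    assert len(ranges) == (n - k) // step + 1


def test_window_too_large_error_names_both_values():
    with pytest.raises(ValueError, match="500.*250|250.*500"):
        slide_windows(250, WindowSpec(2.0, 0.5), FS)


def test_fractional_slide_rounds_to_whole_samples():
    k, step = WindowSpec(0.5, 0.125).to_samples(FS)
    assert (k, step) == (125, 31)


# ---------------------------------------------------------------- band power

def test_in_band_tone_dominates_disjoint_band():
    t = np.arange(int(2 * FS)) / FS
    tone = np.sin(2 * np.pi * 10.0 * t)
    alpha, beta = DEFAULT_BANDS
    assert band_power(tone, alpha, FS) > 10 * band_power(tone, beta, FS)


def test_zero_signal_zero_power():
    assert band_power(np.zeros(500), DEFAULT_BANDS[0], FS) == 0.0


def test_white_noise_power_ratio_tracks_bandwidth(rng):
    """Flat spectrum: alpha(4 Hz)/beta(10 Hz) integrated power ~ 0.4."""
    x = rng.standard_normal(int(10 * FS))
    alpha, beta = DEFAULT_BANDS
    ratio = band_power(x, alpha, FS) / band_power(x, beta, FS)
    assert abs(ratio - 0.4) < 0.08


def test_band_beyond_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        band_power(np.ones(100), BandDefinition("hf", 100.0, 130.0), FS)


# ---------------------------------------------------------------- scaling

def test_scaler_brings_max_into_decade():
    s = PowerScaler().fit(np.array([0.0042, 0.001]))
    assert s.factor_ == pytest.approx(1e3)
    assert s.transform(np.array([0.0042]))[0] == pytest.approx(4.2)
    assert PowerScaler().fit(np.array([7.0])).factor_ == 1.0


def test_scaler_train_only_allows_test_overflow():
    s = PowerScaler().fit(np.array([0.5]))  # factor 10
    assert s.transform(np.array([3.0]))[0] == pytest.approx(30.0)


def test_scaler_all_zero_warns_identity():
    with pytest.warns(RuntimeWarning):
        s = PowerScaler().fit(np.zeros(4))
    assert s.factor_ == 1.0


# ---------------------------------------------------------------- pearson

def test_pearson_reference_cases(rng):
    x = rng.standard_normal(50)
    assert pearson(x, x) == pytest.approx(1.0)
    assert pearson(x, -x) == pytest.approx(-1.0)
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 7.0])
    assert pearson(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)


def test_pearson_zero_variance_warns_zero():
    with pytest.warns(RuntimeWarning):
        assert pearson(np.ones(10), np.arange(10.0)) == 0.0


finite_vectors = arrays(
    np.float64,
    st.integers(3, 20),
    elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
)


@given(x=finite_vectors, scale=st.floats(1e-3, 1e3))
def test_pearson_scale_invariant_and_antisymmetric(x, scale):
    y = np.sin(np.arange(x.size))  # fixed nonconstant partner
    if np.ptp(x) == 0:
        return
    r = pearson(x, y)
    assert pearson(scale * x, y) == pytest.approx(r, abs=1e-9)
    assert pearson(-x, y) == pytest.approx(-r, abs=1e-9)


# ---------------------------------------------------------------- jaccard

def test_jaccard_printed_identities(rng):
    a = rng.standard_normal(32)
    assert jaccard_index(a, a) == pytest.approx(1.0, abs=1e-12)
    assert jaccard_index(a, -a) == pytest.approx(-1.0 / 3.0, abs=1e-12)
    assert jaccard_distance(a, a) == pytest.approx(0.0, abs=1e-12)
    assert jaccard_distance(a, -a) == pytest.approx(4.0 / 3.0, abs=1e-12)
    assert jaccard_index(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0


def test_jaccard_undefined_for_two_zero_vectors():
    with pytest.raises(ValueError):
        jaccard_index(np.zeros(3), np.zeros(3))


@given(a=finite_vectors, b=finite_vectors)
@settings(max_examples=500)
def test_jaccard_bounds_and_complement(a, b):
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    if a @ a + b @ b == 0:  # zero or underflowing-to-zero vectors
        return
    j = jaccard_index(a, b)
    jd = jaccard_distance(a, b)
    assert -1.0 / 3.0 - 1e-9 <= j <= 1.0 + 1e-9
    assert -1e-9 <= jd <= 4.0 / 3.0 + 1e-9
    assert jd + j == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------- extraction

@pytest.fixture(scope="module")
def one_trial():
    paradigm = feedback_paradigm(n_runs=1, trials_per_class_per_run=1)
    return generate_session(paradigm, SignalModel(), seed=5)[0]


@pytest.mark.parametrize(
    "window_s,slide_s,mode,expected_shape",
    [
        (2.0, 0.5, "correlation", (3, 9)),
        (2.0, 0.5, "none", (3, 6)),
        (3.0, 3.0, "jaccard", (1, 9)),
    ],
)
def test_extract_features_shapes(one_trial, window_s, slide_s, mode, expected_shape):
    seq = extract_features(one_trial, WindowSpec(window_s, slide_s), interaction_mode=mode)
    assert seq.values.shape == expected_shape
    assert np.all(np.isfinite(seq.values))
    assert len(seq.feature_names) == expected_shape[1]
    # band powers first, fixed electrode x band order
    assert seq.feature_names[:6] == (
        "C3_alpha", "C3_beta", "Cz_alpha", "Cz_beta", "C4_alpha", "C4_beta",
    )


def test_interactions_computed_on_raw_windows(one_trial):
    """The correlation column for C3-C4 must equal pearson() of the raw
    windowed samples, not a function of band powers."""
    seq = extract_features(one_trial, WindowSpec(2.0, 0.5), interaction_mode="correlation")
    expected = pearson(one_trial.signal[0, 0:500], one_trial.signal[2, 0:500])
    assert seq.values[0, 8] == pytest.approx(expected, abs=1e-12)


def test_flatten_round_trip(one_trial):
    seq = extract_features(one_trial, WindowSpec(1.0, 0.5), interaction_mode="jaccard")
    flat = flatten_for_static(seq)
    assert flat.shape == (seq.n_windows * len(seq.feature_names),)
    np.testing.assert_array_equal(flat.reshape(seq.values.shape), seq.values)


def test_extraction_deterministic(one_trial):
    a = extract_features(one_trial, WindowSpec(1.0, 0.5), interaction_mode="correlation")
    b = extract_features(one_trial, WindowSpec(1.0, 0.5), interaction_mode="correlation")
    np.testing.assert_array_equal(a.values, b.values)


def test_features_frame_layout(small_session):
    seqs = [
        extract_features(t, WindowSpec(1.0, 1.0), interaction_mode="jaccard")
        for t in small_session[:4]
    ]
    df = features_to_frame(seqs)
    assert len(df) == 4 * 3
    assert "C3_C4_jaccard" in df.columns
    assert set(df.label) <= {"left", "right"}
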