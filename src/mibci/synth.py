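"""Synthetic motor-imagery EEG cohorts.

Emulates the trial structure of a cue-based two-class (left- vs right-hand)
motor-imagery paradigm recorded from three bipolar electrodes (C3, Cz, C4)
at 250 Hz: feedback sessions with four runs of 20 randomized trials per
class (160 trials), screening sessions with six runs of 10 per class
(120 trials).  Only the 3-6 s imagery segment of each trial is emitted by
default.

The signal model is deliberately simple but carries the three statistical
structures the downstream analysis relies on:

* class-dependent mu-band event-related desynchronization (ERD): the
  mu-rhythm amplitude on the electrode contralateral to the imagined hand
  is attenuated by a per-class, per-channel factor;
* class-dependent inter-channel coupling: a shared narrow-band latent
  source is mixed into an electrode pair with a per-class coefficient,
  producing class-informative correlation between the raw signals without
  changing their marginal band power (the mixing is variance-preserving);
* subject-level random effects: a per-subject additive shift on the ERD
  depths, giving the block structure a randomized-blocks ANOVA assumes.

All randomness is driven by counter-based streams derived from a single
root seed (``numpy.random.SeedSequence`` spawn keys), so cohorts are
bit-reproducible and independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4")

__all__ = [
    "CHANNELS",
    "ParadigmConfig",
    "SignalModel",
    "Trial",
    "feedback_paradigm",
    "screening_paradigm",
    "generate_session",
    "generate_cohort",
    "write_session_csv",
    "read_session_csv",
]


class ConfigError(ValueError):
    """Raised for malformed paradigm or signal-model configuration."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial-structure parameters of one recording session.

    Defaults describe a feedback session: four runs, 20 randomized trials
    per class and run, 250 Hz sampling, imagery between 3 and 6 s after
    trial onset.
    """

    n_runs: int = 4
    trials_per_class_per_run: int = 20
    classes: tuple[str, ...] = ("left", "right")
    fs: float = 250.0
    segment_start_s: float = 3.0
    segment_end_s: float = 6.0
    session_kind: str = "feedback"
    trial_duration_s: float = 8.0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.trials_per_class_per_run < 1:
            raise ConfigError(
                f"n_runs and trials_per_class_per_run must be >= 1, got "
                f"{self.n_runs} and {self.trials_per_class_per_run}"
            )
        if len(self.classes) < 2 or len(set(self.classes)) != len(self.classes):
            raise ConfigError(f"classes must be distinct labels, got {self.classes!r}")
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if not (0 <= self.segment_start_s < self.segment_end_s <= self.trial_duration_s):
            raise ConfigError(
                f"need 0 <= segment_start_s < segment_end_s <= trial_duration_s, got "
                f"[{self.segment_start_s}, {self.segment_end_s}] in {self.trial_duration_s}"
            )

    @property
    def trials_per_session(self) -> int:
        return self.n_runs * len(self.classes) * self.trials_per_class_per_run

    @property
    def n_segment_samples(self) -> int:
        return int(round((self.segment_end_s - self.segment_start_s) * self.fs))


def feedback_paradigm(**overrides) -> ParadigmConfig:
    """Feedback-session paradigm: 4 runs x 2 classes x 20 trials = 160."""
    return ParadigmConfig(**{"session_kind": "feedback", **overrides})


def screening_paradigm(**overrides) -> ParadigmConfig:
    """Screening-session paradigm: 6 runs x 2 classes x 10 trials = 120."""
    defaults = {"n_runs": 6, "trials_per_class_per_run": 10, "session_kind": "screening"}
    return ParadigmConfig(**{**defaults, **overrides})


def _default_erd_depth() -> dict[str, dict[str, float]]:
    # Contralateral mu attenuation: right-hand imagery suppresses C3,
    # left-hand imagery suppresses C4; mild bilateral effect on Cz.
    return {
        "left": {"C3": 1.0, "Cz": 0.95, "C4": 0.85},
        "right": {"C3": 0.85, "Cz": 0.95, "C4": 1.0},
    }


def _default_coupling() -> dict[str, float]:
    return {"left": 0.0, "right": 0.3}


@dataclass(frozen=True)
class SignalModel:
    """Generative parameters of the synthetic EEG.

    Each channel is background 1/f^alpha noise plus narrow-band filtered
    noise in the mu and beta bands.  ``erd_depth[label][channel]``
    multiplies the mu amplitude during imagery (values in (0, 1]; 1 means
    no desynchronization).  ``coupling_strength[label]`` is the Pearson
    correlation induced between the mu components of ``coupling_pair`` by
    a shared latent source; the mixing preserves each channel's marginal
    mu power, so coupling is informative through correlation/Jaccard
    features only.  ``subject_effect_sd`` is the standard deviation of a
    per-subject additive shift applied to every ERD depth (clipped back
    to (0, 1]), which creates the between-subject block variability.
    """

    background_sd: float = 1.5
    one_over_f_exponent: float = 1.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (15.0, 25.0)
    mu_amplitude: float = 1.0
    beta_amplitude: float = 0.5
    erd_depth: Mapping[str, Mapping[str, float]] = field(default_factory=_default_erd_depth)
    coupling_strength: Mapping[str, float] = field(default_factory=_default_coupling)
    coupling_pair: tuple[str, str] = ("C3", "C4")
    subject_effect_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ConfigError(f"background_sd must be >= 0, got {self.background_sd}")
        for name, band in (("mu_band", self.mu_band), ("beta_band", self.beta_band)):
            lo, hi = band
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must satisfy 0 < low < high, got {band}")
        for label, per_ch in self.erd_depth.items():
            for ch, depth in per_ch.items():
                if not (0 < depth <= 1):
                    raise ConfigError(
                        f"erd_depth[{label!r}][{ch!r}] must lie in (0, 1], got {depth}"
                    )
        for label, g in self.coupling_strength.items():
            if not (0 <= g < 1):
                raise ConfigError(
                    f"coupling_strength[{label!r}] must lie in [0, 1), got {g}"
                )
        if self.subject_effect_sd < 0:
            raise ConfigError(f"subject_effect_sd must be >= 0, got {self.subject_effect_sd}")
        for ch in self.coupling_pair:
            if ch not in CHANNELS:
                raise ConfigError(f"coupling_pair channel {ch!r} not in {CHANNELS}")


@dataclass
class Trial:
    """One labeled multichannel segment (rows ordered C3, Cz, C4)."""

    signal: np.ndarray  # (n_channels, n_samples)
    label: str
    fs: float
    subject_id: str
    session_id: int
    trial_index: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("trial signal must be channels x samples")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("trial signal contains non-finite values")


def _colored_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian 1/f^alpha noise of unit variance, synthesized spectrally."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    coeffs = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(coeffs, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise with support restricted to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    coeffs = np.zeros(freqs.size, dtype=complex)
    coeffs[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(coeffs, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _shifted_depth(depth: float, shift: float) -> float:
    return float(np.clip(depth + shift, 0.05, 1.0))


def _synthesize_trial(
    rng: np.random.Generator,
    paradigm: ParadigmConfig,
    model: SignalModel,
    label: str,
    erd_shift: float,
    full_trial: bool,
) -> np.ndarray:
    """One trial's multichannel signal; imagery modulation applies inside
    the imagery segment only (which, by default, is all that is emitted)."""
    if full_trial:
        n = int(round(paradigm.trial_duration_s * paradigm.fs))
        seg = slice(
            int(round(paradigm.segment_start_s * paradigm.fs)),
            int(round(paradigm.segment_end_s * paradigm.fs)),
        )
    else:
        n = paradigm.n_segment_samples
        seg = slice(0, n)

    g = float(model.coupling_strength.get(label, 0.0))
    shared_mu = _narrowband_noise(rng, n, paradigm.fs, model.mu_band)

    signal = np.empty((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        background = model.background_sd * _colored_noise(
            rng, n, paradigm.fs, model.one_over_f_exponent
        )
        mu = _narrowband_noise(rng, n, paradigm.fs, model.mu_band)
        if ch in model.coupling_pair and g > 0:
            # variance-preserving mix: corr(mu_a, mu_b) = g, marginal power unchanged
            mu = np.sqrt(1.0 - g) * mu + np.sqrt(g) * shared_mu
        beta = _narrowband_noise(rng, n, paradigm.fs, model.beta_band)

        depth = _shifted_depth(model.erd_depth.get(label, {}).get(ch, 1.0), erd_shift)
        mu_gain = np.full(n, model.mu_amplitude)
        mu_gain[seg] = model.mu_amplitude * depth

        signal[ci] = background + mu_gain * mu + model.beta_amplitude * beta
    return signal


def _child_seed(root: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(root, spawn_key=tuple(key))


def generate_session(
    paradigm: ParadigmConfig,
    model: SignalModel,
    subject_id: str = "S01",
    session_id: int = 0,
    seed: int = 0,
    erd_shift: float = 0.0,
    full_trial: bool = False,
) -> list[Trial]:
    """Generate one session's trials, balanced and randomized within runs.

    ``erd_shift`` is the subject-level random effect (drawn by
    :func:`generate_cohort`); pass 0 for a population-average subject.
    Trials are segmented to the imagery interval unless ``full_trial``.
    """
    trials: list[Trial] = []
    idx = 0
    for run in range(paradigm.n_runs):
        labels = list(paradigm.classes) * paradigm.trials_per_class_per_run
        order_rng = np.random.default_rng(_child_seed(seed, session_id, run))
        order_rng.shuffle(labels)
        for t, label in enumerate(labels):
            trial_rng = np.random.default_rng(_child_seed(seed, session_id, run, t + 1))
            sig = _synthesize_trial(trial_rng, paradigm, model, label, erd_shift, full_trial)
            trials.append(
                Trial(
                    signal=sig,
                    label=label,
                    fs=paradigm.fs,
                    subject_id=subject_id,
                    session_id=session_id,
                    trial_index=idx,
                )
            )
            idx += 1
    return trials


def generate_cohort(
    n_subjects: int,
    sessions_per_subject: int,
    paradigm: ParadigmConfig,
    model: SignalModel,
    seed: int = 0,
) -> dict[str, list[list[Trial]]]:
    """Generate a cohort keyed by subject id ("S01", "S02", ...).

    Each subject's ERD-depth shift is drawn once and reused across that
    subject's sessions, so subjects act as blocks in the downstream ANOVA.
    """
    if n_subjects < 1:
        raise ConfigError(f"n_subjects must be >= 1, got {n_subjects}")
    cohort: dict[str, list[list[Trial]]] = {}
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        shift_rng = np.random.default_rng(_child_seed(seed, 1, s))
        erd_shift = float(shift_rng.normal(0.0, model.subject_effect_sd))
        sessions = []
        for sess in range(sessions_per_subject):
            sess_seed = int(_child_seed(seed, 2, s, sess).generate_state(1)[0])
            sessions.append(
                generate_session(
                    paradigm,
                    model,
                    subject_id=subject_id,
                    session_id=sess,
                    seed=sess_seed,
                    erd_shift=erd_shift,
                )
            )
        cohort[subject_id] = sessions
    return cohort


def write_session_csv(trials: Sequence[Trial], path) -> None:
    """Long-format CSV: subject, session, trial, label, channel, sample_index, value."""
    frames = []
    for tr in trials:
        n = tr.signal.shape[1]
        for ci, ch in enumerate(CHANNELS):
            frames.append(
                pd.DataFrame(
                    {
                        "subject": tr.subject_id,
                        "session": tr.session_id,
                        "trial": tr.trial_index,
                        "label": tr.label,
                        "channel": ch,
                        "sample_index": np.arange(n),
                        "value": tr.signal[ci],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_session_csv(path, fs: float = 250.0) -> list[Trial]:
    """Inverse of :func:`write_session_csv`."""
    df = pd.read_csv(path)
    trials = []
    for (subj, sess, idx), grp in df.groupby(["subject", "session", "trial"], sort=True):
        label = grp["label"].iloc[0]
        mat = np.vstack(
            [
                grp[grp.channel == ch].sort_values("sample_index")["value"].to_numpy()
                for ch in CHANNELS
            ]
        )
        trials.append(
            Trial(
                signal=mat,
                label=str(label),
                fs=fs,
                subject_id=str(subj),
                session_id=int(sess),
                trial_index=int(idx),
            )
        )
    trials.sort(key=lambda t: (t.subject_id, t.session_id, t.trial_index))
    return trials


def load_gdf_session(path, subject_id: str, session_id: int):  # pragma: no cover
    """Adapter stub for real GDF session files (BCI Competition IV 2b layout).

    Returns the same ``list[Trial]`` contract as :func:`generate_session`.
    Delegates to ``mne.io.read_raw_gdf`` when mne is available; reading the
    real accession is outside the tested surface of this package.
    """
    raise NotImplementedError(
        "GDF ingestion is an optional adapter; install mne and segment the "
        "3-6 s imagery interval into Trial objects with rows C3, Cz, C4."
    )
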