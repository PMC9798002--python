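"""Cross-validated accuracy evaluation.

The protocol mirrors the study design: five independently seeded rounds
of stratified 3-fold cross-validation; within each outer training set a
stratified 4-fold grid search tunes the classifier hyperparameters
(LDA covariance shrinkage; HCRF hidden-state count and L2 strength);
the winner is refit on the full outer training set and scored on the
held-out fold.  Band-power scaling (PowerScaler) is fitted on training
trials only and reused on the test fold, so no test information leaks
into preprocessing or model selection.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import hcrf as hcrf_mod
from . import lda as lda_mod
from .features import (
    DEFAULT_BANDS,
    FeatureSequence,
    PowerScaler,
    WindowSpec,
    extract_features,
)
from .synth import Trial

__all__ = [
    "ConfusionMatrix",
    "Condition",
    "FoldResult",
    "CVResult",
    "accuracy",
    "nested_cv",
    "run_condition_grid",
    "summarize_results",
    "full_condition_grid",
]

N_BAND_FEATURES = 6  # 3 electrodes x 2 bands, always the leading columns

MIN_TRIALS_PER_CLASS = 12  # 3 outer x 4 inner stratified folds must be populated


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = tuple(classes)
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[classes.index(t), classes.index(p)] += 1
        return cls(counts=counts, classes=classes)


def accuracy(H: ConfusionMatrix) -> float:
    """p0 = trace(H) / N_s, the fraction of correctly classified trials."""
    if H.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(H.counts)) / H.total


@dataclass(frozen=True)
class Condition:
    """One evaluated configuration: classifier x interaction mode x window geometry."""

    classifier: str  # 'lda' | 'hcrf'
    interaction_mode: str  # 'none' | 'correlation' | 'jaccard'
    window_s: float
    slide_s: float
    lda_shrinkage_grid: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1)
    hcrf_states_grid: tuple[int, ...] = (2, 3, 4)
    hcrf_reg_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    hcrf_restarts: int = 3
    hcrf_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.classifier not in ("lda", "hcrf"):
            raise ValueError(f"classifier must be 'lda' or 'hcrf', got {self.classifier!r}")

    @property
    def label(self) -> str:
        return f"{self.classifier}|{self.interaction_mode}|w{self.window_s}|s{self.slide_s}"

    def hyper_grid(self) -> list[dict]:
        """Candidate hyperparameters, ordered so that ties in the inner CV
        resolve to the smallest (most regularized / fewest states)."""
        if self.classifier == "lda":
            return [{"shrinkage": v} for v in sorted(self.lda_shrinkage_grid, reverse=True)]
        return [
            {"n_states": m, "reg": c}
            for m in sorted(self.hcrf_states_grid)
            for c in sorted(self.hcrf_reg_grid, reverse=True)
        ]


@dataclass
class FoldResult:
    round: int
    fold: int
    confusion: ConfusionMatrix
    accuracy: float
    hyperparams: dict


@dataclass
class CVResult:
    subject: str
    condition: Condition
    folds: list[FoldResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))


def _scale_band_powers(
    train: list[FeatureSequence], others: list[FeatureSequence]
) -> tuple[list[FeatureSequence], list[FeatureSequence], float]:
    """Fit the power-of-ten scaler on training band powers only; apply to all."""
    scaler = PowerScaler().fit(
        np.concatenate([s.values[:, :N_BAND_FEATURES].reshape(-1) for s in train])
    )

    def apply(seqs):
        out = []
        for s in seqs:
            v = s.values.copy()
            v[:, :N_BAND_FEATURES] = scaler.transform(v[:, :N_BAND_FEATURES])
            out.append(s.with_values(v))
        return out

    return apply(train), apply(others), float(scaler.factor_)


def _fit_and_score(
    train: list[FeatureSequence],
    test: list[FeatureSequence],
    condition: Condition,
    hyper: dict,
    seed: int,
) -> tuple[ConfusionMatrix, float]:
    """Scale (train-fitted), fit one classifier, score the held-out trials.

    Returns the confusion matrix and the scaling factor actually used, so
    callers can audit that it came from the training fold alone.
    """
    train_s, test_s, factor = _scale_band_powers(train, test)
    y_train = [s.label for s in train_s]
    y_test = [s.label for s in test_s]
    classes = tuple(sorted(set(y_train)))

    if condition.classifier == "lda":
        Xtr = np.stack([s.flatten() for s in train_s])
        Xte = np.stack([s.flatten() for s in test_s])
        params = lda_mod.fit_lda(Xtr, y_train, shrinkage=hyper["shrinkage"])
        preds = lda_mod.predict_lda(params, Xte)
    else:
        params = hcrf_mod.train_hcrf(
            train_s,
            n_states=hyper["n_states"],
            reg=hyper["reg"],
            seed=seed,
            restarts=condition.hcrf_restarts,
            max_iter=condition.hcrf_max_iter,
        )
        preds = [hcrf_mod.predict_hcrf(params, s) for s in test_s]

    return ConfusionMatrix.from_predictions(y_test, preds, classes), factor


def _fold_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence(root, spawn_key=tuple(key)).generate_state(1)[0])


def _select_hyper(
    seqs: list[FeatureSequence],
    labels: np.ndarray,
    condition: Condition,
    n_inner: int,
    seed: int,
) -> dict:
    """Stratified inner-CV grid search; ties go to the earliest (smallest)
    grid entry via a strict improvement rule."""
    grid = condition.hyper_grid()
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed % (2**32))
    splits = list(skf.split(np.zeros(len(seqs)), labels))
    best, best_acc = None, -np.inf
    for gi, hyper in enumerate(grid):
        accs = []
        for fi, (tr, va) in enumerate(splits):
            H, _ = _fit_and_score(
                [seqs[i] for i in tr],
                [seqs[i] for i in va],
                condition,
                hyper,
                seed=_fold_seed(seed, gi, fi),
            )
            accs.append(accuracy(H))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best, best_acc = hyper, mean_acc
    return best


def nested_cv(
    trials: list[Trial],
    condition: Condition,
    seed: int = 0,
    rounds: int = 5,
    n_outer: int = 3,
    n_inner: int = 4,
    bands=DEFAULT_BANDS,
) -> CVResult:
    """Rounds of stratified outer 3-fold CV with inner 4-fold tuning.

    Features are extracted once per trial (unscaled); every per-fold fit
    re-fits scaling and hyperparameters from that fold's training trials.
    """
    labels = np.array([t.label for t in trials])
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < MIN_TRIALS_PER_CLASS:
        raise ValueError(
            f"nested CV needs >= {MIN_TRIALS_PER_CLASS} trials per class, "
            f"smallest class has {counts.min()}"
        )
    spec = WindowSpec(condition.window_s, condition.slide_s)
    seqs = [
        extract_features(t, spec, bands=bands, interaction_mode=condition.interaction_mode)
        for t in trials
    ]
    subject = trials[0].subject_id

    folds: list[FoldResult] = []
    for r in range(rounds):
        round_seed = _fold_seed(seed, r)
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=round_seed % (2**32))
        for fi, (tr, te) in enumerate(skf.split(np.zeros(len(seqs)), labels)):
            train = [seqs[i] for i in tr]
            hyper = _select_hyper(
                train, labels[tr], condition, n_inner, seed=_fold_seed(seed, r, fi, 1)
            )
            H, factor = _fit_and_score(
                train, [seqs[i] for i in te], condition, hyper, seed=_fold_seed(seed, r, fi, 2)
            )
            folds.append(
                FoldResult(
                    round=r,
                    fold=fi,
                    confusion=H,
                    accuracy=accuracy(H),
                    hyperparams={**hyper, "power_scale_factor": factor},
                )
            )
    return CVResult(subject=subject, condition=condition, folds=folds)


def _condition_seed(root: int, condition: Condition) -> int:
    """Seed stream independent per condition: keyed by a hash of the
    condition label, so adding conditions never perturbs existing rows."""
    key = zlib.crc32(condition.label.encode())
    return _fold_seed(root, 3, key)


def run_condition_grid(
    cohort: dict[str, list[list[Trial]]],
    conditions: list[Condition],
    seed: int = 0,
    rounds: int = 5,
    pool_sessions: bool = True,
) -> pd.DataFrame:
    """Evaluate every condition on every subject; one row per (subject,
    condition, round, fold).  Sessions are pooled per subject before CV
    (``pool_sessions=False`` evaluates each session separately and keeps
    the per-session accuracies as extra rows)."""
    records = []
    for cond in conditions:
        cond_seed = _condition_seed(seed, cond)
        for si, subject in enumerate(sorted(cohort)):
            sessions = cohort[subject]
            groups = [list(itertools.chain.from_iterable(sessions))] if pool_sessions else sessions
            for gi, trials in enumerate(groups):
                result = nested_cv(
                    trials, cond, seed=_fold_seed(cond_seed, si, gi), rounds=rounds
                )
                for f in result.folds:
                    records.append(
                        {
                            "subject": subject,
                            "classifier": cond.classifier,
                            "interaction_mode": cond.interaction_mode,
                            "window_s": cond.window_s,
                            "slide_s": cond.slide_s,
                            "session_group": gi,
                            "round": f.round,
                            "fold": f.fold,
                            "accuracy": f.accuracy,
                            "hyperparams": json.dumps(f.hyperparams, sort_keys=True),
                        }
                    )
    return pd.DataFrame.from_records(records)


def summarize_results(detail: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per subject x condition (rounds and folds averaged)."""
    keys = ["subject", "classifier", "interaction_mode", "window_s", "slide_s"]
    return detail.groupby(keys, as_index=False)["accuracy"].mean()


def full_condition_grid(**overrides) -> list[Condition]:
    """The full comparison grid: window sizes 0.5/1/2 s plus the whole 3 s
    segment, slide sizes 0.125/0.25/0.5 s, both interaction measures, both
    classifiers (48 conditions)."""
    windows = (0.5, 1.0, 2.0, 3.0)
    slides = (0.125, 0.25, 0.5)
    modes = ("correlation", "jaccard")
    classifiers = ("lda", "hcrf")
    return [
        Condition(classifier=c, interaction_mode=m, window_s=w, slide_s=s, **overrides)
        for w in windows
        for s in slides
        for m in modes
        for c in classifiers
    ]
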