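# Methods

## Scope and design

`mibci` asks one question of two-class motor-imagery EEG: do instantaneous
inter-electrode interaction features (Pearson correlation, generalized Jaccard
distance) add class information beyond sliding-window band powers, under a
static (LDA) and a dynamic (HCRF) classifier? Since the real recordings are an
external accession, the analysis runs on synthetic cohorts whose generator is
first-class, tested code; the generator's job is to reproduce the *paradigm
structure* and the three *statistical structures* the analysis relies on, not
physiological waveforms.

## Synthetic EEG generator

Each trial's imagery segment (3–6 s at 250 Hz, 750 samples, channels C3, Cz,
C4) is a sum of three zero-mean components per channel:

1. **Background**: 1/f^α Gaussian noise (α = 1 by default), synthesized in the
   frequency domain and scaled to `background_sd` (default 1.5). Matches the
   broadband spectral shape of EEG without claiming realism.
2. **Band oscillations**: narrow-band Gaussian noise in the mu (8–12 Hz) and
   beta (15–25 Hz) bands (unit variance, amplitudes 1.0 and 0.5). Filtered
   noise rather than sinusoids gives band-power estimators realistic variance.
3. **Event-related desynchronization**: during imagery the mu amplitude of
   each channel is multiplied by `erd_depth[label][channel]` ∈ (0, 1].
   Defaults: 0.85 contralateral to the imagined hand (C3 for right, C4 for
   left), 0.95 on Cz, 1.0 elsewhere.

**Inter-channel coupling.** A shared latent mu-band source `z` is mixed into
the pair C3–C4 as `√(1−g)·n_ch + √g·z`, so `g = coupling_strength[label]` *is*
the correlation induced between the two channels' mu components while each
marginal band power is preserved in expectation. Defaults `{left: 0, right:
0.3}`: coupling carries class information through correlation/Jaccard features
only, independently of band power — the lever the whole analysis isolates.

**Subject random effects.** One additive shift per subject (SD
`subject_effect_sd` = 0.08, clipped so depths stay in (0, 1]) applied to all
ERD depths, reused across that subject's sessions. This produces the
between-subject accuracy spread that makes subjects meaningful blocks in the
ANOVA. The defaults were fixed once so that the band-power-only classifier
lands in the 0.70–0.77 accuracy range typical of real two-class motor
imagery; nothing in the generator adapts to downstream results.

**Seeding.** All streams derive from one root seed via counter-based
`SeedSequence` spawn keys — subject shifts from `(1, subject)`, session trial
streams from `(2, subject, session)`, per-trial signals from
`(session, run, trial)` — so cohorts are bit-reproducible and independent of
generation order.

What the generator does **not** emulate: eye-movement artifacts, non-Gaussian
or non-stationary noise, volume-conduction mixing, feedback-driven adaptation,
electrode drift. Passing tests therefore show that the pipeline detects the
modeled effect structure correctly, not that it would perform identically on
recorded EEG.

## Features

Windows are half-open sample ranges `[i, i+k)` stepped by `Δi`; second-valued
window/slide sizes are rounded to the nearest whole sample (a 0.125 s slide at
250 Hz is 31 samples). Band power is a Welch estimate (Hann, 50 % overlap,
`nperseg = min(len, 2·fs)`) integrated over the band by the trapezoid rule —
the estimator is a package choice; at 0.5 s windows it degrades gracefully to
a single tapered periodogram. Band powers are brought "to an order of
magnitude 10" by one power-of-ten factor fitted so the training-set maximum
lies in [1, 10); the factor is fitted per training fold and reused unchanged
on held-out data (test values may exceed 10). Interpreting that scaling rule
as a single global, train-fitted factor (rather than per-feature) is a
documented interpretation of an ambiguous convention.

Interaction features are computed on the **raw windowed samples** (not band
envelopes): Pearson after per-window demeaning (the definition assumes
zero-mean variables; a zero-variance window yields 0 with a warning rather
than aborting a fold), Jaccard on the raw windows, since the dot-product form
is mean-sensitive by construction. Both inputs of a zero vector make the
Jaccard ratio 0/0 and raise an error.

## Classifiers

**LDA.** Class means, empirical priors, pooled within-class covariance shrunk
as `(1−λ)Σ + λ·D`, where `D` is `diag(Σ)` with zero entries floored — the
floor keeps a degenerate zero-spread fit invertible for λ > 0. λ defaults to
the grid {0, 10⁻³, 10⁻², 10⁻¹} tuned by inner CV, because flattened
sliding-window vectors can be long relative to trial counts. The discriminant
uses a Cholesky factorization (stable log-determinant, no explicit inverse);
a singular unregularized fit raises an error advising shrinkage. Ties break
to the lexicographically first label.

**HCRF.** Linear chain, disjoint hidden-state sets per label (cross-label
transitions are structurally absent, equivalent to −∞ weights). Feature
functions are first-order: per-state observation weights, per-state biases,
within-label transition weights. All path sums run in log space (never a
linear-space partition function); gradients come from forward–backward state
and transition marginals. Training minimizes the L2-penalized negative
conditional log-likelihood with L-BFGS-B (gradient tolerance 1e−5, ≤ 500
iterations) from N(0, 0.1²) seeded initial weights; the hidden-path
likelihood is non-convex, so the best of (default) 3 restarts wins. Hidden
states per label m defaults to 3, tuned over {2, 3, 4}; L2 strength over
{0.1, 1, 10}. None of m, initialization, or regularization is dictated by the
underlying study design, so all are exposed and tuned.

## Evaluation protocol

Five independently seeded rounds of stratified 3-fold cross-validation;
within each outer training set a stratified 4-fold grid search picks the
hyperparameters (ties go to the most regularized / fewest states), the winner
is refit on the full outer training set and scored on the held-out fold.
Stratification is a package choice that preserves the 50/50 class balance at
3-fold on 160-trial sessions. Power scaling and hyperparameter selection see
training trials only; the per-fold scale factor is recorded so leakage is
auditable. Sessions of one subject are pooled before CV (a flag evaluates
per-session instead). Each condition draws its seed stream from a hash of its
own description, so adding conditions never changes existing rows.

## Statistics

"One-way randomized blocks ANOVA" is implemented as the standard additive
two-way fixed-effects decomposition (treatment + block); blocks are reported,
not tested. The multi-way variant adds main effects only (no window×slide
interaction; a flag can include replication-permitting designs). Balanced
designs are required and missing cells are an error. Sums of squares come
from marginal means; F = MS_effect/MS_residual with d.f. (a−1) and
N−1−Σ(aᵢ−1)−(b−1) (= (a−1)(b−1) for one observation per cell). Sums of
squares below 1e−12 of SS_total are treated as numerically zero so that
noise-free degenerate tables give F = 0 rather than 0/0 artifacts.

Tukey–Kramer uses the studentized range with the blocked residual mean
square: `q = |m̄ᵢ − m̄ⱼ| / √(MS_res/2 · (1/nᵢ + 1/nⱼ))`. For two levels the
decision coincides with the blocked F-test. The **level-vs-overall** variant
compares each level mean against the grand mean one-sidedly — a level is
flagged only when it *exceeds* the grand mean by more than the critical
margin, and levels at or below it receive p = 1. This nonstandard rule is
implemented exactly as described by the study it follows and is documented as
such; the standard all-pairs procedure is also available. p-values are kept
at machine precision; "<0.001" formatting is applied only when rendering
reports.

## Problem sizes in the shipped tests

The suite's end-to-end check runs a 9-subject, 3-feedback-session cohort
(480 trials per subject) through a reduced protocol — 2 CV rounds, single
hyperparameter per classifier (LDA λ = 0.01; HCRF m = 2, L2 = 1, 1 restart,
≤ 100 iterations), LDA on the whole 3-s window and HCRF on 1 s windows with
0.5 s slides — once with the default class-dependent coupling and once with
coupling removed. These sizes are the package's scaled-down analysis
configuration; the full 48-condition grid (windows 0.5/1/2/3 s × slides
0.125/0.25/0.5 s × two measures × two classifiers, 5 rounds) is available
through `mibci run-all --preset full-grid` and is hours-scale.

## Known limitations

- The generator's coupling acts on one electrode pair (C3–C4) and one band;
  real functional connectivity is broader-band and montage-dependent.
- The blocked ANOVA treats CV-estimated accuracies as observations; their
  estimation noise enters the residual, which is conservative.
- `statsmodels`/`mne` are not runtime dependencies; the optional GDF adapter
  is an interface stub and real-data ingestion is untested by design.
- Statistical unit tests assert properties of sampling distributions; they
  use fixed seeds and thresholds set at ≥3σ, so a generator change that
  shifts those distributions will surface as test failures rather than silent
  drift.
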