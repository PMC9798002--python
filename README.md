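# mibci

Do instantaneous inter-electrode interactions help classify motor imagery?

`mibci` is a tested pipeline for a two-class (left- vs right-hand) motor-imagery
EEG question: whether adding **interaction features between electrode pairs** —
Pearson correlation or a generalized (dot-product) Jaccard distance — to
sliding-window band-power features improves classification under a **static**
classifier (linear discriminant analysis, LDA) and a **dynamic** one (hidden
conditional random field, HCRF), and whether the improvement survives a
randomized-blocks ANOVA with Tukey–Kramer post-hoc comparison across subjects.

It is aimed at BCI researchers who want the full chain — paradigm-faithful
synthetic EEG cohorts, feature extraction, both classifiers, nested
cross-validation, and the blocked statistical comparison — as reusable,
seed-reproducible library code.

## The measures and models

For two windowed electrode signals (vectors) `A`, `B`:

- Pearson correlation `ρ(x, y) = E[xy] / (σ_x σ_y)` (windows demeaned);
- generalized Jaccard index `J(A, B) = A·B / (‖A‖² + ‖B‖² − A·B)`, bounded in
  `[−1/3, 1]` with the extremes at `B = −A` and `B = A`;
- Jaccard distance `J_D = 1 − J = ‖A−B‖² / (‖A‖² + ‖B‖² − A·B)` in `[0, 4/3]`.

Per sliding window (`k` samples, displaced by `Δi`), features are the alpha/mu
(8–12 Hz) and beta (15–25 Hz) band powers of C3, Cz, C4, optionally followed by
one interaction value per pair (C3–Cz, C4–Cz, C3–C4).

The static model scores a flattened per-trial vector with the Gaussian
discriminant `δ_k(x) = −½ log|Σ| − ½ (x−μ_k)ᵀ Σ⁻¹ (x−μ_k) + log π_k` with a
shared (shrunk) covariance Σ, so decision boundaries are linear. The dynamic
model is a linear-chain HCRF: each label `y` owns a disjoint set `H_y` of
hidden states and

```
p(y|x) = (1/Z) Σ_{h∈H_y} Π_t exp( Σ_k θ_k f_k(h_t, h_{t−1}, x_t) )
```

trained by L2-penalized maximum conditional likelihood (forward–backward in
log space, L-BFGS with seeded restarts).

Evaluation is rounds of stratified 3-fold cross-validation with inner 4-fold
hyperparameter tuning; accuracy is `p0 = trace(H)/N_s` of the confusion matrix.
Per-subject accuracies are compared with a randomized-blocks ANOVA (subjects as
blocks) and Tukey–Kramer post-hoc tests, including the one-sided
level-vs-overall-mean variant used to flag which feature condition drives a
significant result.

Because the real recordings are an external accession, the package ships a
first-class synthetic cohort generator that emulates the paradigm (feedback
sessions: 4 runs × 20 randomized trials per class = 160 trials at 250 Hz,
imagery segment 3–6 s) with class-dependent contralateral mu-band ERD,
class-dependent inter-channel coupling, and per-subject random effects.

## Worked example

```python
import numpy as np
from mibci import (SignalModel, feedback_paradigm, generate_cohort,
                   Condition, run_condition_grid, summarize_results,
                   rb_anova_oneway)

cohort = generate_cohort(n_subjects=9, sessions_per_subject=1,
                         paradigm=feedback_paradigm(), model=SignalModel(),
                         seed=42)
conds = [Condition("lda", mode, window_s=3.0, slide_s=3.0,
                   lda_shrinkage_grid=(0.01,))
         for mode in ("none", "correlation")]
detail = run_condition_grid(cohort, conds, seed=42, rounds=2)
summary = summarize_results(detail)
anova = rb_anova_oneway(summary, "accuracy", "interaction_mode", "subject")
print(summary.groupby("interaction_mode").accuracy.mean().round(3))
e = anova.effects[0]
print(f"F = {e.f:.2f}; d.f. = {e.df}; p = {e.p:.4f}")
```

Output:

```
interaction_mode
correlation    0.719
none           0.685
Name: accuracy, dtype: float64
F = 7.59; d.f. = 1; p = 0.0249
```

Adding the C3–Cz/C4–Cz/C3–C4 correlation features lifts mean cross-validated
accuracy from 0.685 to 0.719, and the subject-blocked ANOVA rejects equality
of the two feature conditions at α = 0.05 (F on 1 and 8 degrees of freedom).

A command-line interface wraps the same pipeline:

```
mibci run-all --preset smoke --config cfg.yaml --out results/   # cfg.yaml: "seed: 7"
mibci report --results results/
```

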