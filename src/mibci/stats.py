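"""Randomized-blocks ANOVA and Tukey-Kramer post-hoc comparisons.

Subjects act as blocks: each treatment level (e.g. with/without interaction
features) is observed once (or a balanced number of times) per subject, and
the additive fixed-effects decomposition

    y_{ij} = mu + tau_i (treatment) + beta_j (block) + e_{ij}

removes between-subject variability from the error term.  The "one-way
randomized blocks" model is a two-way additive decomposition in which only
the treatment factor is tested; the multi-way variant adds further main
effects (window size, slide size) with no interaction terms.  Post-hoc
comparisons use the studentized range distribution with the blocked-model
residual mean square (Tukey-Kramer), either all-pairs or each level
against the overall mean (a one-sided variant in which a level is flagged
only when its mean exceeds the grand mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "EffectResult",
    "AnovaResult",
    "rb_anova_oneway",
    "rb_anova_multiway",
    "tukey_kramer",
    "level_vs_overall",
    "format_p",
    "anova_report",
]


@dataclass
class EffectResult:
    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class AnovaResult:
    effects: list[EffectResult]  # tested factors, in input order
    block: EffectResult          # block decomposition (reported, not of interest)
    residual_ss: float
    residual_df: int
    grand_mean: float
    n_obs: int

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _check_balanced(table: pd.DataFrame, factors: list[str], block: str) -> None:
    cells = table.groupby(factors + [block], observed=True).size()
    levels = [table[f].unique() for f in factors] + [table[block].unique()]
    n_expected = int(np.prod([len(l) for l in levels]))
    if len(cells) != n_expected:
        present = set(cells.index)
        missing = [
            combo
            for combo in pd.MultiIndex.from_product(levels)
            if (combo if len(levels) > 1 else combo[0]) not in present
        ]
        raise ValueError(f"missing (factor, block) cells: {missing[:10]}")
    if cells.nunique() != 1:
        raise ValueError("unbalanced design: unequal replication across cells")


def _main_effect_ss(y: np.ndarray, groups: np.ndarray, grand: float) -> tuple[float, int]:
    levels = np.unique(groups)
    ss = 0.0
    for lev in levels:
        sel = groups == lev
        ss += sel.sum() * (y[sel].mean() - grand) ** 2
    return float(ss), len(levels) - 1


def _rb_anova(table: pd.DataFrame, value: str, factors: list[str], block: str) -> AnovaResult:
    if len(factors) < 1:
        raise ValueError("at least one factor required")
    for f in factors + [block]:
        if table[f].nunique() < 2:
            raise ValueError(f"column {f!r} needs >= 2 levels, has {table[f].nunique()}")
    _check_balanced(table, factors, block)

    y = table[value].to_numpy(dtype=float)
    grand = float(y.mean())
    ss_total = float(np.sum((y - grand) ** 2))

    effects = []
    ss_model = 0.0
    df_model = 0
    for f in factors:
        ss, df = _main_effect_ss(y, table[f].to_numpy(), grand)
        effects.append((f, ss, df))
        ss_model += ss
        df_model += df
    ss_block, df_block = _main_effect_ss(y, table[block].to_numpy(), grand)

    ss_res = ss_total - ss_model - ss_block
    df_res = len(y) - 1 - df_model - df_block
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom; design is saturated")
    ms_res = ss_res / df_res
    # roundoff floor: sums of squares below this are numerically zero
    zero_tol = 1e-12 * max(ss_total, np.finfo(float).tiny)

    def make(name, ss, df):
        ms = ss / df
        if ms_res > zero_tol:
            f_stat = ms / ms_res
        else:
            f_stat = 0.0 if ss <= zero_tol else np.inf
        p = float(sp_stats.f.sf(f_stat, df, df_res)) if np.isfinite(f_stat) else 0.0
        return EffectResult(name=name, ss=ss, df=df, ms=ms, f=max(f_stat, 0.0), p=p)

    return AnovaResult(
        effects=[make(n, s, d) for n, s, d in effects],
        block=make(block, ss_block, df_block),
        residual_ss=max(ss_res, 0.0),
        residual_df=df_res,
        grand_mean=grand,
        n_obs=len(y),
    )


def rb_anova_oneway(table: pd.DataFrame, value: str, factor: str, block: str) -> AnovaResult:
    """One treatment factor, subjects as blocks; F = MS_factor / MS_residual
    with (a-1, (a-1)(b-1)) degrees of freedom in the one-observation-per-cell
    case."""
    return _rb_anova(table, value, [factor], block)


def rb_anova_multiway(
    table: pd.DataFrame, value: str, factors: list[str], block: str
) -> AnovaResult:
    """Additive main-effects model (factor1 + factor2 + ... + block), no
    interaction terms; requires a balanced design."""
    return _rb_anova(table, value, list(factors), block)


def tukey_kramer(
    table: pd.DataFrame,
    value: str,
    factor: str,
    block: str,
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """All-pairs comparisons of factor-level means using the studentized
    range with the blocked-ANOVA residual mean square."""
    if anova is None:
        anova = rb_anova_oneway(table, value, factor, block)
    levels = sorted(table[factor].unique().tolist())
    if len(levels) < 2:
        raise ValueError("post-hoc comparison needs >= 2 levels")
    means = table.groupby(factor, observed=True)[value].mean()
    counts = table.groupby(factor, observed=True)[value].size()
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[a] - means[b])
            se = np.sqrt(anova.residual_ms / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
            mean_tol = 1e-9 * (abs(anova.grand_mean) + 1.0)
            if se > 0:
                q = abs(diff) / se
            else:
                q = 0.0 if abs(diff) <= mean_tol else np.inf
            p = float(sp_stats.studentized_range.sf(q, k, anova.residual_df))
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "mean_a": float(means[a]),
                    "mean_b": float(means[b]),
                    "diff": diff,
                    "se": float(se),
                    "q": float(q),
                    "p_adj": min(p, 1.0),
                    "reject": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def level_vs_overall(
    table: pd.DataFrame,
    value: str,
    factor: str,
    block: str,
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """Each level's mean against the overall (grand) mean, one-sided.

    A level is flagged only when its mean exceeds the grand mean by more
    than the Tukey-Kramer critical margin; levels at or below the grand
    mean receive p = 1.  This is the comparison used to mark which
    feature condition drives a significant ANOVA.
    """
    if anova is None:
        anova = rb_anova_oneway(table, value, factor, block)
    levels = sorted(table[factor].unique().tolist())
    if len(levels) < 2:
        raise ValueError("post-hoc comparison needs >= 2 levels")
    means = table.groupby(factor, observed=True)[value].mean()
    counts = table.groupby(factor, observed=True)[value].size()
    n_total = len(table)
    k = len(levels)
    rows = []
    mean_tol = 1e-9 * (abs(anova.grand_mean) + 1.0)  # roundoff floor on means
    for lev in levels:
        diff = float(means[lev] - anova.grand_mean)
        se = np.sqrt(anova.residual_ms / 2.0 * (1.0 / counts[lev] + 1.0 / n_total))
        if diff <= mean_tol:
            q, p = 0.0, 1.0
        else:
            q = diff / se if se > 0 else np.inf
            p = float(sp_stats.studentized_range.sf(q, k, anova.residual_df))
        rows.append(
            {
                "level": lev,
                "mean": float(means[lev]),
                "grand_mean": anova.grand_mean,
                "diff": diff,
                "se": float(se),
                "q": float(q),
                "p": min(p, 1.0),
                "reject": bool(diff > 0 and p < alpha),
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float, threshold: float = 1e-3) -> str:
    """Report-style p-value: values below the threshold render as '<0.001'."""
    if p < threshold:
        return f"<{threshold:g}"
    return f"{p:.3g}"


def anova_report(anova: AnovaResult, title: str = "Randomized-blocks ANOVA") -> str:
    lines = [title, "-" * len(title)]
    for e in anova.effects:
        lines.append(
            f"{e.name}: F = {e.f:.3f}; d.f. = {e.df}; p = {format_p(e.p)}"
        )
    lines.append(
        f"blocks ({anova.block.name}): SS = {anova.block.ss:.6g}; d.f. = {anova.block.df}"
    )
    lines.append(
        f"residual: MS = {anova.residual_ms:.6g}; d.f. = {anova.residual_df}; "
        f"grand mean = {anova.grand_mean:.4f}"
    )
    return "\n".join(lines)
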