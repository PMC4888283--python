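"""Cutoff-point inference: ANOVA and Dunnett many-to-one comparisons.

Each demographic parameter is analysed independently.  Replicate values at
every partial-week horizon are compared against the full-life-table values
(the week-W "control") with a two-sided Dunnett test, the classical
many-to-one procedure controlling familywise error across the W-1
comparisons.  The earliest week from which all later partial weeks are
statistically indistinguishable from the full life table is that
parameter's *cutoff point*: observation past it does not change the
estimate detectably.

Dunnett adjusted p-values are computed by seeded Monte Carlo sampling of
the joint null distribution of the comparison statistics — a multivariate
t with the pairwise correlations n_i n_j / ((n_i + n_0)(n_j + n_0))
implied by the shared control (1/2 under balance) — rather than by table
lookup, so any number of groups and error degrees of freedom is supported
reproducibly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Sequence

import numpy as np

from .truncation import TruncationSeries
from .engine import PARAMETER_NAMES

__all__ = [
    "AnovaResult",
    "DunnettComparison",
    "DunnettResult",
    "CutoffReport",
    "anova_oneway",
    "dunnett_test",
    "assign_letters",
    "find_cutoff",
    "cutoff_analysis",
]

DEFAULT_MC_DRAWS = 200_000


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects one-way ANOVA decomposition."""

    F: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    mse: float
    degenerate: bool  # zero within-group variance everywhere


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from sums of squares.

    Requires at least two groups with at least two values each.  When every
    group is internally constant (SS_within = 0) the F ratio is undefined
    and the result is flagged degenerate.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    grand = np.concatenate(arrays)
    grand_mean = grand.mean()
    ss_between = float(sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = len(arrays) - 1
    df_within = grand.size - len(arrays)
    degenerate = ss_within <= 0.0
    mse = ss_within / df_within
    f_stat = math.inf if degenerate else (ss_between / df_between) / mse
    if degenerate and ss_between == 0.0:
        f_stat = math.nan
    return AnovaResult(
        F=f_stat,
        df_between=df_between,
        df_within=df_within,
        ss_between=ss_between,
        ss_within=ss_within,
        mse=mse,
        degenerate=degenerate,
    )


@lru_cache(maxsize=64)
def _null_max_abs_t(
    group_sizes: tuple[int, ...], df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Sorted Monte Carlo sample of max_i |T_i| under the joint Dunnett null.

    ``group_sizes`` is (n_control, n_1, ..., n_k).  Each draw simulates the
    group means as independent normals with variance 1/n_j and a pooled
    variance estimate S^2 ~ chi^2_df / df, reproducing the equicorrelated
    (correlation n_i/(n_i + n_0) pairwise) multivariate-t null exactly.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(group_sizes, dtype=float)
    means = rng.standard_normal((n_draws, sizes.size)) / np.sqrt(sizes)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    scale = np.sqrt(1.0 / sizes[1:] + 1.0 / sizes[0])
    t = (means[:, 1:] - means[:, :1]) / (s[:, None] * scale[None, :])
    out = np.max(np.abs(t), axis=1)
    out.sort()
    return out


@dataclass(frozen=True)
class DunnettComparison:
    """One treatment-vs-control row of a Dunnett test."""

    label: object          # e.g. the truncation week
    mean_diff: float       # treatment mean - control mean
    statistic: float       # mean_diff / sqrt(MSE (1/n_i + 1/n_0))
    p_adjusted: float
    p_se: float            # Monte Carlo standard error of p_adjusted
    significant: bool
    letter: str            # 'b' significant, 'a' not


@dataclass(frozen=True)
class DunnettResult:
    parameter: str
    comparisons: tuple[DunnettComparison, ...]
    anova: AnovaResult
    alpha: float
    df: int
    n_draws: int
    seed: int
    dropped_labels: tuple = ()

    def comparison(self, label) -> DunnettComparison:
        for c in self.comparisons:
            if c.label == label:
                return c
        raise KeyError(label)


def dunnett_test(
    treatments: Sequence[Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    seed: int = 0,
    labels: Sequence | None = None,
    parameter: str = "",
    n_draws: int = DEFAULT_MC_DRAWS,
) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparison of k treatments vs control.

    The pooled error variance (MSE) comes from the one-way ANOVA over all
    k + 1 groups with N - k - 1 degrees of freedom.  Adjusted p-values are
    ``P(max_j |T_j| >= |t_i|)`` under the joint null, estimated from a
    seeded Monte Carlo sample (``n_draws`` draws, standard error reported
    per comparison); ``significant`` means adjusted p < alpha.

    Unbalanced group sizes are handled through the exact pairwise
    correlation structure n_i/(n_i + n_0); a note is logged because the
    study design this mirrors is balanced.
    """
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(t, dtype=float) for t in treatments
    ]
    if labels is None:
        labels = list(range(1, len(treatments) + 1))
    if len(labels) != len(treatments):
        raise ValueError("labels must match treatments")
    sizes = tuple(int(g.size) for g in groups)
    if len(set(sizes)) > 1:
        warnings.warn(
            "unbalanced groups: using pairwise correlations n_i/(n_i + n_0)",
            stacklevel=2,
        )
    anova = anova_oneway(groups)
    df = anova.df_within  # N - (k + 1) groups pooled
    null_sample = _null_max_abs_t(sizes, df, n_draws, seed)
    control_mean = groups[0].mean()
    comparisons = []
    for label, grp in zip(labels, groups[1:]):
        diff = float(grp.mean() - control_mean)
        denom = math.sqrt(anova.mse * (1.0 / grp.size + 1.0 / groups[0].size))
        if denom == 0.0:
            stat = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        else:
            stat = diff / denom
        # P(max |T| >= |t|) from the sorted null sample
        idx = np.searchsorted(null_sample, abs(stat), side="left")
        p = float((null_sample.size - idx) / null_sample.size)
        if math.isinf(stat):
            p = 0.0
        p_se = math.sqrt(max(p * (1.0 - p), 0.0) / null_sample.size)
        sig = p < alpha
        comparisons.append(
            DunnettComparison(
                label=label,
                mean_diff=diff,
                statistic=stat,
                p_adjusted=p,
                p_se=p_se,
                significant=sig,
                letter="b" if sig else "a",
            )
        )
    return DunnettResult(
        parameter=parameter,
        comparisons=tuple(comparisons),
        anova=anova,
        alpha=alpha,
        df=df,
        n_draws=n_draws,
        seed=seed,
    )


def assign_letters(result: DunnettResult, n_weeks: int) -> Dict[int, str]:
    """Significance letters per week, 'a' for the control (full) week.

    'b' marks weeks whose parameter differs significantly from the full
    life table; 'a' marks indistinguishable weeks — the convention of the
    classical weekly life-table reports.
    """
    letters = {int(c.label): c.letter for c in result.comparisons}
    letters[n_weeks] = "a"
    return letters


@dataclass(frozen=True)
class CutoffReport:
    """Cutoff point of one demographic parameter.

    ``first_nonsignificant_week`` is the smallest week w such that every
    week from w to W-1 is non-significant versus the full table (W when no
    such week exists); ``last_significant_week`` is 0 when no week is
    significant.  Both life-cycle-fraction conventions are reported:
    ``pct_last_significant`` = 100 (w - 1)/W (the "> w-1 weeks" reading)
    and ``pct_first_nonsignificant`` = 100 w / W.
    """

    parameter: str
    n_weeks: int
    first_nonsignificant_week: int
    last_significant_week: int
    pct_last_significant: float
    pct_first_nonsignificant: float


def find_cutoff(result: DunnettResult, n_weeks: int) -> CutoffReport:
    """Locate the cutoff week from the Dunnett significance pattern."""
    sig = {int(c.label): c.significant for c in result.comparisons}
    weeks = sorted(sig)
    first_nonsig = n_weeks
    for w in weeks:
        if all(not sig[v] for v in weeks if v >= w):
            first_nonsig = w
            break
    last_sig = max((w for w in weeks if sig[w]), default=0)
    return CutoffReport(
        parameter=result.parameter,
        n_weeks=n_weeks,
        first_nonsignificant_week=first_nonsig,
        last_significant_week=last_sig,
        pct_last_significant=100.0 * (first_nonsig - 1) / n_weeks,
        pct_first_nonsignificant=100.0 * first_nonsig / n_weeks,
    )


@dataclass(frozen=True)
class CutoffAnalysis:
    """Dunnett results, letters and cutoff reports for all parameters."""

    dunnett: Dict[str, DunnettResult]
    letters: Dict[str, Dict[int, str]]
    cutoffs: Dict[str, CutoffReport]
    alpha: float
    seed: int


def cutoff_analysis(
    series: TruncationSeries,
    alpha: float = 0.05,
    seed: int = 0,
    n_draws: int = DEFAULT_MC_DRAWS,
) -> CutoffAnalysis:
    """Run the full per-parameter Dunnett/cutoff procedure on a series.

    Week W across replicates is the control; weeks 1..W-1 are the
    treatments.  Weeks where any replicate's value is undefined are dropped
    from that parameter's comparison set with a warning.  No multiplicity
    correction is applied across the seven parameters.
    """
    n_weeks = series.n_weeks
    if n_weeks < 2:
        raise ValueError("cutoff analysis needs at least two weekly horizons")
    dunnett: Dict[str, DunnettResult] = {}
    letters: Dict[str, Dict[int, str]] = {}
    cutoffs: Dict[str, CutoffReport] = {}
    for name in PARAMETER_NAMES:
        control = series.values(name, n_weeks)
        if np.any(np.isnan(control)):
            warnings.warn(
                f"{name}: undefined in the full life table; skipped", stacklevel=2
            )
            continue
        weeks, groups, dropped = [], [], []
        for w in range(1, n_weeks):
            vals = series.values(name, w)
            if np.any(np.isnan(vals)):
                dropped.append(w)
            else:
                weeks.append(w)
                groups.append(vals)
        if dropped:
            warnings.warn(
                f"{name}: week(s) {dropped} dropped (undefined replicate values)",
                stacklevel=2,
            )
        if not weeks:
            continue
        res = dunnett_test(
            groups,
            control,
            alpha=alpha,
            seed=seed,
            labels=weeks,
            parameter=name,
            n_draws=n_draws,
        )
        res = DunnettResult(
            parameter=res.parameter,
            comparisons=res.comparisons,
            anova=res.anova,
            alpha=res.alpha,
            df=res.df,
            n_draws=res.n_draws,
            seed=res.seed,
            dropped_labels=tuple(dropped),
        )
        dunnett[name] = res
        letters[name] = assign_letters(res, n_weeks)
        cutoffs[name] = find_cutoff(res, n_weeks)
    return CutoffAnalysis(
        dunnett=dunnett, letters=letters, cutoffs=cutoffs, alpha=alpha, seed=seed
    )
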