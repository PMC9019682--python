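"""Across-study aggregation and the comparative statistics of the compendium.

Aggregation is the unweighted mean of study means with its across-study
SEM (sample SD / sqrt(n)) — the "Mean ± (n = studies) SEM" convention.
Comparative statistics are percent differences, fold changes, absolute
deltas, Student t tests (pooled by default, Welch by flag) and one-way
ANOVA followed by Dunnett's many-to-one test, whose adjusted p-values come
from a seeded Monte-Carlo reference distribution of the max-|t| statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AggregateCore", "Comparison", "TTestResult", "DunnettResult",
    "aggregate_study_means", "percent_difference", "percent_increase",
    "fold_change", "absolute_delta", "unpaired_t", "paired_t",
    "anova_dunnett", "dunnett_null_sample", "matches_printed",
]

_P_FLOOR = 1e-300  # underflow-safe minimum for degenerate zero-variance cases


@dataclass(frozen=True)
class AggregateCore:
    mean: float
    sem: Optional[float]
    n_studies: int


@dataclass(frozen=True)
class Comparison:
    kind: Literal["percent_lower", "percent_higher", "fold_change", "absolute_delta"]
    reference_group: str
    test_group: str
    statistic: float
    p_value: Optional[float] = None
    test: Literal["unpaired_t", "paired_t", "anova_dunnett", "none"] = "none"

    def __post_init__(self) -> None:
        if self.kind.startswith("percent") and self.statistic < 0:
            raise ValueError(f"{self.kind} must be >= 0, got {self.statistic}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class DunnettResult:
    f_stat: float
    f_p: float
    t_stats: Tuple[float, ...]
    adjusted_p: Tuple[float, ...]
    unadjusted_p: Tuple[float, ...] = field(default=())


def aggregate_study_means(values: Sequence[float]) -> AggregateCore:
    """Unweighted mean of study means; SEM = sample SD (n−1) / sqrt(n).

    SEM is undefined (None) for a single study.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("aggregate_study_means requires at least one value")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("values must be finite")
    n = len(vals)
    mean = math.fsum(vals) / n
    if n == 1:
        return AggregateCore(mean=mean, sem=None, n_studies=1)
    var = math.fsum((v - mean) ** 2 for v in vals) / (n - 1)
    return AggregateCore(mean=mean, sem=math.sqrt(var / n), n_studies=n)


def percent_difference(test_mean: float, reference_mean: float) -> float:
    """100 × (reference − test)/reference; positive = test below reference."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (reference_mean - test_mean) / reference_mean


def percent_increase(test_mean: float, reference_mean: float) -> float:
    """100 × (test − reference)/reference; positive = test above reference."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (test_mean - reference_mean) / reference_mean


def fold_change(test_mean: float, reference_mean: float) -> float:
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0 for a fold change")
    return test_mean / reference_mean


def absolute_delta(a: float, b: float) -> float:
    """a − b, in the shared unit of the inputs."""
    return a - b


def _degenerate_t(mean_a: float, mean_b: float, df: float) -> TTestResult:
    # zero pooled variance: equal means -> no evidence; unequal -> certainty
    if mean_a == mean_b:
        return TTestResult(t=0.0, df=df, p=1.0)
    t = math.copysign(math.inf, mean_a - mean_b)
    return TTestResult(t=t, df=df, p=_P_FLOOR)


def unpaired_t(sample_a: Sequence[float], sample_b: Sequence[float],
               equal_variance: bool = True) -> TTestResult:
    """Two-sample Student t (pooled variance by default; Welch by flag)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return _degenerate_t(a.mean(), b.mean(), df=len(a) + len(b) - 2)
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=max(float(res.pvalue), _P_FLOOR))


def paired_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Paired Student t on within-pair differences."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if d.var(ddof=1) == 0.0:
        return _degenerate_t(float(d.mean()), 0.0, df=len(d) - 1)
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), df=float(len(d) - 1),
                       p=max(float(res.pvalue), _P_FLOOR))


def dunnett_null_sample(n_control: int, n_treatments: Sequence[int], df: int,
                        n_draws: int = 50_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo null sample of the Dunnett max-|t| statistic.

    Under the global null the many-to-one t statistics share the control
    mean and the pooled variance: group means are N(0, 1/n_g) and the
    pooled s² is chi²(df)/df, independent of the means.  Returns
    ``n_draws`` realizations of max_k |T_k|.
    """
    rng = np.random.default_rng(seed)
    nt = np.array(n_treatments, dtype=float)
    z0 = rng.standard_normal(n_draws) / math.sqrt(n_control)
    zt = rng.standard_normal((len(nt), n_draws)) / np.sqrt(nt)[:, None]
    s2 = rng.chisquare(df, n_draws) / df
    se = np.sqrt(s2[None, :] * (1.0 / nt[:, None] + 1.0 / n_control))
    return np.abs((zt - z0[None, :]) / se).max(axis=0)


def anova_dunnett(control: Sequence[float], treatments: Sequence[Sequence[float]],
                  n_draws: int = 50_000, seed: int = 0) -> DunnettResult:
    """One-way ANOVA F plus Dunnett many-to-one comparisons vs control.

    The Dunnett adjustment uses a seeded Monte-Carlo null: simulate
    ``n_draws`` realizations of the max over treatments of the absolute
    many-to-one t statistic (shared control, pooled variance), and take the
    adjusted p of treatment j as P(max_k |T_k| >= |t_j|).  Adjusted p is
    floored at the unadjusted two-sided t p, which is an exact lower bound.
    """
    if len(treatments) < 1:
        raise ValueError("need at least one treatment group (>= 2 groups total)")
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(t, dtype=float) for t in treatments]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")

    n = [len(g) for g in groups]
    N, kk = sum(n), len(groups)
    df = N - kk
    ss_within = math.fsum(float(((g - g.mean()) ** 2).sum()) for g in groups)

    if ss_within == 0.0:
        if all(g.mean() == groups[0].mean() for g in groups):
            m = len(treatments)
            return DunnettResult(f_stat=0.0, f_p=1.0, t_stats=(0.0,) * m,
                                 adjusted_p=(1.0,) * m, unadjusted_p=(1.0,) * m)
        s2p = _P_FLOOR  # degenerate: distinct means, zero spread
    else:
        s2p = ss_within / df

    f_stat, f_p = stats.f_oneway(*groups)
    if ss_within == 0.0:
        f_stat, f_p = math.inf, _P_FLOOR

    t_obs = np.array([
        (g.mean() - groups[0].mean()) / math.sqrt(s2p * (1 / len(g) + 1 / n[0]))
        for g in groups[1:]])

    max_abs_t = dunnett_null_sample(n[0], n[1:], df, n_draws=n_draws, seed=seed)

    unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)
    adj = np.array([
        (1 + np.count_nonzero(max_abs_t >= abs(t))) / (n_draws + 1)
        for t in t_obs])
    adj = np.clip(np.maximum(adj, unadj), _P_FLOOR, 1.0)
    return DunnettResult(
        f_stat=float(f_stat), f_p=max(float(f_p), _P_FLOOR),
        t_stats=tuple(float(t) for t in t_obs),
        adjusted_p=tuple(float(p) for p in adj),
        unadjusted_p=tuple(float(p) for p in np.maximum(unadj, _P_FLOOR)),
    )


def matches_printed(computed: float, printed: str) -> bool:
    """Printed-precision agreement: within one unit in the last printed digit.

    The tables print rounded (sometimes truncated) values computed from
    unrounded study means, so agreement is accepted when the recomputed
    value lies within one ulp of the printed figure — e.g. 40.2597 matches
    a printed "40.2" (truncation) as well as "40.3" (rounding).
    """
    printed = printed.strip()
    val = float(printed)
    if "." in printed:
        decimals = len(printed.split(".")[1])
        ulp = 10.0 ** (-decimals)
    else:
        ulp = 1.0
    return abs(computed - val) <= ulp * (1 + 1e-9)
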