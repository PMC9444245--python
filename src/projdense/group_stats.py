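"""Descriptive and inferential statistics for group comparisons.

Summaries are reported as mean ± SD with the sample (n-1) standard
deviation. Group comparison is a one-way fixed-effects ANOVA followed by
Fisher's least-significant-difference (LSD) post hoc: unadjusted pairwise
t tests pooling the ANOVA mean-square error, with the within-group degrees
of freedom. Homogeneity of variances is checked with Levene's test
(mean-centered); the check is reported alongside the ANOVA and never gates
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class GroupData:
    """A labeled group of per-animal values."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) == 0:
            raise ValueError(f"group {self.label!r} is empty")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    mse: float
    ss_between: float
    ss_within: float
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    mean_difference: float
    t: float
    p: float


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    A single value has undefined sample SD and returns ``nan`` for it.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sd requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


def as_groups(data) -> list[GroupData]:
    """Coerce a mapping or sequence of GroupData into a list of GroupData."""
    if isinstance(data, dict):
        return [GroupData(label=k, values=tuple(v)) for k, v in data.items()]
    return [g if isinstance(g, GroupData) else GroupData(*g) for g in data]


def homogeneity_test(groups) -> tuple[float, float]:
    """Levene's test (center = mean) for equality of group variances.

    Groups of constant values give statistic 0 (p = 1) rather than a
    division error.
    """
    gs = as_groups(groups)
    if len(gs) < 2 or any(g.n < 2 for g in gs):
        raise ValueError("homogeneity test needs >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g.values) for g in gs]
    # Levene's z-values are |x - group mean|; if every z is constant within
    # and across groups (e.g. all groups constant) the statistic is 0/0 —
    # report exact homogeneity instead of dividing by zero.
    zs = [np.abs(a - a.mean()) for a in arrays]
    allz = np.concatenate(zs)
    if np.ptp(allz) == 0:
        return 0.0, 1.0
    stat, p = _sps.levene(*arrays, center="mean")
    return float(stat), float(p)


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    With zero within-group variance and unequal means the F statistic is
    infinite; the result is flagged ``degenerate`` and p reported as 0.0.
    """
    gs = as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = [g.n for g in gs]
    n_total = sum(ns)
    if n_total <= k:
        raise ValueError("ANOVA needs more observations than groups")
    allv = np.concatenate([np.asarray(g.values) for g in gs])
    grand = allv.mean()
    ssb = float(sum(g.n * (g.mean - grand) ** 2 for g in gs))
    ssw = float(sum(((np.asarray(g.values) - g.mean) ** 2).sum() for g in gs))
    dfb, dfw = k - 1, n_total - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0.0:
        if msb == 0.0:
            f, p, degenerate = 0.0, 1.0, False
        else:
            f, p, degenerate = float("inf"), 0.0, True
    else:
        f = msb / msw
        p = float(_sps.f.sf(f, dfb, dfw))
        degenerate = False
    return AnovaResult(
        f=float(f),
        df_between=dfb,
        df_within=dfw,
        p=p,
        mse=msw,
        ss_between=ssb,
        ss_within=ssw,
        group_labels=tuple(g.label for g in gs),
        group_means=tuple(g.mean for g in gs),
        degenerate=degenerate,
    )


def lsd_posthoc(groups, anova: AnovaResult | None = None) -> list[PairwiseResult]:
    """Fisher's LSD pairwise comparisons using the pooled ANOVA MSE.

    For each pair, ``t = (mean_i - mean_j) / sqrt(MSE (1/n_i + 1/n_j))``
    with the ANOVA's within-group degrees of freedom; p values are
    two-sided and deliberately unadjusted (that is the LSD procedure).
    """
    gs = as_groups(groups)
    if anova is None:
        anova = one_way_anova(gs)
    if tuple(g.label for g in gs) != anova.group_labels:
        raise ValueError("ANOVA was computed on different groups")
    out = []
    for gi, gj in combinations(gs, 2):
        diff = gi.mean - gj.mean
        if anova.mse == 0.0:
            t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(anova.mse * (1.0 / gi.n + 1.0 / gj.n))
            p = float(2.0 * _sps.t.sf(abs(t), anova.df_within))
        out.append(
            PairwiseResult(pair=(gi.label, gj.label), mean_difference=float(diff), t=float(t), p=p)
        )
    return out
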