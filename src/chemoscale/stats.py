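"""Group comparison of steady-state scalars (viability, rates) across
reactor setups: one-way ANOVA with Bonferroni-adjusted pairwise t-tests,
plus the STD% (coefficient of variation) used for steady-state tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSeries:
    """A labelled series of steady-state sampling values for one condition
    (e.g. a sparger type / kLa setting)."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 values")


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    p_value: float
    significant: bool


def one_way_anova(groups: Sequence[GroupSeries]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    f, p = sps.f_oneway(*[np.asarray(g.values) for g in groups])
    return float(f), float(p)


def bonferroni_threshold(family_alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance threshold alpha / k, rounded to 4
    decimals for display (0.05 over 3 comparisons -> 0.0167)."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    return round(family_alpha / n_comparisons, 4)


def pairwise_posthoc(groups: Sequence[GroupSeries],
                     family_alpha: float = 0.05) -> list[PairwiseResult]:
    """Pooled-variance two-sample t-test for every group pair; a pair is
    significant when its p-value falls below alpha divided by the number
    of pairs."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pairs = list(combinations(groups, 2))
    threshold = family_alpha / len(pairs)
    out = []
    for a, b in pairs:
        p = float(sps.ttest_ind(a.values, b.values, equal_var=True).pvalue)
        out.append(PairwiseResult(pair=(a.label, b.label), p_value=p,
                                  significant=p < threshold))
    return out


def std_percent(values: Sequence[float]) -> float:
    """STD% = 100 * sample standard deviation / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; STD% undefined")
    return float(100.0 * v.std(ddof=1) / m)
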