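"""Population summaries of copy-number calls and between-population t-tests.

Summaries report per-paralog mean/SD copy numbers (sample SD, n-1
denominator), the ratio-class frequency spectrum, and gene-pool shares (the
fraction of all gene copies in the population that are NCF1B, NCF1, NCF1C).
Pairwise comparisons use the two-sample t-test — pooled-variance Student by
default, Welch as an option — computable either from raw per-individual
copy numbers or from published summary statistics (mean, SD, n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "TTestMethod",
    "GroupStats",
    "TTestResult",
    "PopulationSummary",
    "summarize",
    "summarize_populations",
    "two_sample_t",
    "compare_populations",
]

PARALOGS = ("b", "n", "c")


class TTestMethod(str, Enum):
    student_pooled = "student_pooled"
    welch = "welch"


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group (enough for a t-test)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError(f"need n >= 2 per group, got {self.n}")
        if self.sd < 0:
            raise InputError(f"SD must be >= 0, got {self.sd}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupStats":
        arr = np.asarray(values, dtype=float)
        return cls(float(arr.mean()), float(arr.std(ddof=1)), len(arr))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: TTestMethod
    degenerate: bool = False


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    n: int
    n_no_call: int
    mean: dict[str, float]          # paralog -> mean copies
    sd: dict[str, float]            # paralog -> sample SD
    class_frequencies: dict[str, float]  # ratio class label -> proportion
    gene_pool_shares: dict[str, float]   # paralog -> share of all copies

    @property
    def empty(self) -> bool:
        return self.n == 0


def summarize(calls: pd.DataFrame, population: str = "all") -> PopulationSummary:
    """Summarise one population's calls (frame with b, n, c, class, no_call).

    No-call samples are excluded from all statistics and counted separately.
    An empty population yields an explicit empty-summary marker.
    """
    if "no_call" in calls.columns:
        ok = calls.loc[~calls["no_call"].astype(bool)]
        n_no_call = int(calls["no_call"].astype(bool).sum())
    else:
        ok, n_no_call = calls, 0
    if len(ok) == 0:
        return PopulationSummary(population, 0, n_no_call, {}, {}, {}, {})

    counts = ok[list(PARALOGS)].astype(float)
    mean = {p: float(counts[p].mean()) for p in PARALOGS}
    sd = {p: float(counts[p].std(ddof=1)) if len(ok) > 1 else 0.0 for p in PARALOGS}
    if "class" in ok.columns:
        freq = (ok["class"].value_counts(normalize=True)).to_dict()
    else:
        labels = counts.apply(lambda r: f"{int(r.b + r.c)}:{int(r.n)}", axis=1)
        freq = labels.value_counts(normalize=True).to_dict()
    total_mean = sum(mean.values())
    shares = {p: mean[p] / total_mean for p in PARALOGS}
    return PopulationSummary(population, len(ok), n_no_call, mean, sd,
                             {str(k): float(v) for k, v in freq.items()}, shares)


def summarize_populations(
    calls: pd.DataFrame, population_col: str = "population"
) -> dict[str, PopulationSummary]:
    return {
        str(pop): summarize(sub, str(pop))
        for pop, sub in calls.groupby(population_col, sort=True)
    }


def two_sample_t(
    group1: GroupStats | Sequence[float],
    group2: GroupStats | Sequence[float],
    method: TTestMethod = TTestMethod.student_pooled,
) -> TTestResult:
    """Two-sided two-sample t-test from raw values or summary statistics.

    Degenerate case: both groups with zero variance — equal means give
    t = 0, p = 1; unequal means give p = 0 flagged ``degenerate``.
    """
    g1 = group1 if isinstance(group1, GroupStats) else GroupStats.from_values(group1)
    g2 = group2 if isinstance(group2, GroupStats) else GroupStats.from_values(group2)

    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return TTestResult(0.0, g1.n + g2.n - 2, 1.0, method, degenerate=True)
        sign = math.copysign(1.0, g1.mean - g2.mean)
        return TTestResult(sign * math.inf, g1.n + g2.n - 2, 0.0, method, degenerate=True)

    equal_var = method is TTestMethod.student_pooled
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    if equal_var:
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TTestResult(float(res.statistic), df, float(res.pvalue), method)


def compare_populations(
    summaries: Mapping[str, PopulationSummary],
    method: TTestMethod = TTestMethod.student_pooled,
    correction: str = "none",
) -> pd.DataFrame:
    """All pairwise per-paralog tests between populations.

    ``correction``: "none" (default, mirroring uncorrected pairwise
    reporting) or "bonferroni" (p multiplied by the number of tests,
    capped at 1).
    """
    if correction not in ("none", "bonferroni"):
        raise InputError(f"unknown correction {correction!r}")
    names = {"b": "NCF1B", "n": "NCF1", "c": "NCF1C"}
    rows = []
    pairs = list(itertools.combinations(sorted(summaries), 2))
    for pop1, pop2 in pairs:
        s1, s2 = summaries[pop1], summaries[pop2]
        for p in PARALOGS:
            res = two_sample_t(
                GroupStats(s1.mean[p], s1.sd[p], s1.n),
                GroupStats(s2.mean[p], s2.sd[p], s2.n),
                method,
            )
            rows.append((pop1, pop2, names[p], res.t, res.df, res.p))
    out = pd.DataFrame(rows, columns=["pop1", "pop2", "paralog", "t", "df", "p"])
    if correction == "bonferroni":
        out["p"] = (out["p"] * len(out)).clip(upper=1.0)
    return out
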