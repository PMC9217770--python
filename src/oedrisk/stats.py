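"""Cohort comparison statistics.

Per organ, group EARs are summarized as mean +/- sample SD (n-1 denominator)
and compared pairwise with the two-sided Welch (unequal-variance) t-test;
raw p-values are Bonferroni-multiplied by the number of comparisons in the
family *without* capping at 1, so adjusted values above 1 are reported as
such.  Shapiro-Wilk normality screening is advisory: it is reported but never
gates the t-test.  Significance is called at 0.05 on the adjusted value.

The Welch variant was adopted because reverse-engineering the published
comparison table shows the near-zero and the >1 adjusted cells are jointly
consistent with Welch degrees of freedom but not with the pooled test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import GROUPS, ORGANS

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "DEFAULT_PAIRS",
    "CBCT_PSEUDO_GROUP",
    "SIGNIFICANCE_LEVEL",
    "normality_check",
    "welch_from_summary",
    "welch_from_samples",
    "bonferroni",
    "build_comparison_table",
    "auxiliary_compare",
]

#: Pseudo-group: the conventional-linac PBI patients with daily-CBCT dose added.
CBCT_PSEUDO_GROUP = "PBI_CTL_CBCT"

#: The four published comparison columns, in report order.
DEFAULT_PAIRS = (
    ("PBI_CTL", "PBI_MRL"),
    ("PBI_CTL", "WBI_CTL"),
    ("WBI_CTL", "PBI_MRL"),
    (CBCT_PSEUDO_GROUP, "PBI_MRL"),
)

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupSummary:
    organ: str
    group: str
    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.organ}/{self.group}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"{self.organ}/{self.group}: negative SD")


@dataclass(frozen=True)
class ComparisonResult:
    """One organ x group-pair Welch test with uncapped Bonferroni adjustment."""

    organ: str
    pair: tuple[str, str]
    t: float
    df: float
    p_raw: float
    m: int

    @property
    def p_adjusted(self) -> float:
        return bonferroni(self.p_raw, self.m)

    @property
    def significant(self) -> bool:
        return self.p_adjusted < SIGNIFICANCE_LEVEL


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; advisory only.

    Raises for n < 3 and for zero-variance (degenerate) samples.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 values, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance; normality test is undefined")
    stat, p = sps.shapiro(x)
    return float(stat), float(p)


def welch_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float, float]:
    """Two-sided Welch t-test from summary statistics.

    Returns ``(t, df, p_raw)`` with Welch-Satterthwaite degrees of freedom

        df = (va + vb)^2 / (va^2/(n_a-1) + vb^2/(n_b-1)),  v = sd^2 / n.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        raise ValueError("both group variances are zero; t-test is undefined")
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_from_samples(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch test from raw samples; identical to the summary form by definition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def bonferroni(p_raw: float, m: int) -> float:
    """Uncapped Bonferroni adjustment: ``m * p_raw``, may exceed 1."""
    if not 0 < p_raw <= 1:
        raise ValueError("p_raw must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return m * p_raw


def build_comparison_table(
    ears: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    organs: Sequence[str] = ORGANS,
    m: int | None = None,
) -> tuple[list[GroupSummary], list[ComparisonResult]]:
    """Group summaries and pairwise Welch comparisons per organ.

    Parameters
    ----------
    ears : DataFrame
        Tidy EAR matrix with columns ``patient_id``, ``group``, ``organ``,
        ``ear``; groups may include the CBCT pseudo-group.
    pairs : sequence of (group_a, group_b)
        Comparison columns; the Bonferroni family is the pairs within one
        organ, ``m = len(pairs)`` unless overridden.
    """
    required = {"patient_id", "group", "organ", "ear"}
    if not required <= set(ears.columns):
        raise ValueError(f"EAR table needs columns {sorted(required)}")
    m = len(pairs) if m is None else m
    groups_needed = {g for pair in pairs for g in pair}
    counts = ears.groupby("group")["patient_id"].nunique()
    for g in groups_needed:
        if g not in counts.index or counts[g] < 2:
            raise ValueError(f"group {g!r} is missing or has fewer than 2 patients")

    summaries: list[GroupSummary] = []
    results: list[ComparisonResult] = []
    group_order = [g for g in (*GROUPS, CBCT_PSEUDO_GROUP) if g in set(ears["group"])]
    for organ in organs:
        sub = ears[ears["organ"] == organ]
        if sub.empty:
            raise ValueError(f"no EAR values for organ {organ!r}")
        by_group = {g: s["ear"].to_numpy() for g, s in sub.groupby("group")}
        for g in group_order:
            x = by_group[g]
            summaries.append(GroupSummary(organ, g, x.size, float(x.mean()), float(x.std(ddof=1))))
        for pair in pairs:
            t, df, p = welch_from_samples(by_group[pair[0]], by_group[pair[1]])
            results.append(ComparisonResult(organ, tuple(pair), t, df, p, m))
    return summaries, results


def auxiliary_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    correction_m: int = 1,
    label: str = "auxiliary",
    pair: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Welch comparison of an auxiliary quantity (e.g. PTV volume, Dmax)."""
    t, df, p = welch_from_samples(values_a, values_b)
    return ComparisonResult(label, pair, t, df, p, correction_m)
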