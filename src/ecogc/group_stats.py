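"""Rank-based group comparisons and the order-level phylogenetic screen.

Mann-Whitney tests use the exact null distribution for small tie-free
samples (combined n <= 20 by default) and the normal approximation with
tie and continuity corrections otherwise.  The order-level screen runs
all pairwise Mann-Whitney tests among taxonomic orders with enough
observations, Bonferroni-adjusts over the number of pairs, and declares
"no signal" when no adjusted p-value falls below alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .species_io import TraitDataset

__all__ = [
    "RankTestResult",
    "OrderSummary",
    "PhyloScreenResult",
    "mann_whitney",
    "one_tailed_mr_gill_comparison",
    "bonferroni_adjust",
    "normality_screen",
    "phylo_signal_screen",
]

#: Largest combined sample size for which the exact null is enumerated.
EXACT_THRESHOLD = 20

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U for the first sample, with the p-value and method."""

    u_statistic: float
    n1: int
    n2: int
    alternative: str
    p_value: float
    method: str  # "exact" | "normal_approx"


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    *,
    exact_threshold: int = EXACT_THRESHOLD,
    continuity: bool = True,
) -> RankTestResult:
    """Mann-Whitney U test of ``a`` against ``b``.

    ``alternative="greater"`` tests whether values in ``a`` tend to
    exceed those in ``b``.  U is the statistic of the first sample,
    computed from midranks; 0 <= U <= n1*n2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= exact_threshold and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=_ALTERNATIVES[alternative],
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return RankTestResult(
        u_statistic=float(res.statistic),
        n1=int(a.size),
        n2=int(b.size),
        alternative=alternative,
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
    )


def one_tailed_mr_gill_comparison(
    m_values: Sequence[float], nm_values: Sequence[float]
) -> RankTestResult:
    """One-tailed migratory-vs-non-migratory comparison (M > NM a priori)."""
    return mann_whitney(m_values, nm_values, alternative="greater")


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Multiply each p-value by the number of tests ``m``, capping at 1."""
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
        out.append(min(p * m, 1.0))
    return out


def normality_screen(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if values.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n=5000")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class OrderSummary:
    """Per-order distribution summary for box-plot style reporting."""

    order_name: str
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


@dataclass
class PhyloScreenResult:
    verdict: str  # "no signal" | "signal" | "untestable"
    summaries: list[OrderSummary]
    pairwise: list[dict] = field(default_factory=list)
    untested_orders: list[str] = field(default_factory=list)
    alpha: float = 0.05


def _summarize(name: str, vals: np.ndarray) -> OrderSummary:
    return OrderSummary(
        order_name=name,
        n=int(vals.size),
        median=float(np.median(vals)),
        q1=float(np.percentile(vals, 25)),
        q3=float(np.percentile(vals, 75)),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
    )


def phylo_signal_screen(
    dataset: TraitDataset,
    *,
    min_order_size: int = 3,
    alpha: float = 0.05,
) -> PhyloScreenResult:
    """Screen for trait differences among taxonomic orders.

    All pairwise Mann-Whitney tests among orders with at least
    ``min_order_size`` species, Bonferroni-adjusted over the number of
    pairs.  Verdict is "signal" iff any adjusted p < alpha; with fewer
    than two testable orders the screen is "untestable".
    """
    by_order: dict[str, list[float]] = {}
    for rec in dataset:
        by_order.setdefault(rec.order, []).append(rec.trait_value)

    arrays = {k: np.asarray(v, dtype=float) for k, v in by_order.items()}
    summaries = [_summarize(k, v) for k, v in sorted(arrays.items())]
    testable = sorted(k for k, v in arrays.items() if v.size >= min_order_size)
    untested = sorted(set(arrays) - set(testable))

    if len(testable) < 2:
        return PhyloScreenResult(
            verdict="untestable",
            summaries=summaries,
            untested_orders=untested,
            alpha=alpha,
        )

    pairs = list(itertools.combinations(testable, 2))
    raw = [
        mann_whitney(arrays[o1], arrays[o2], alternative="two_sided")
        for o1, o2 in pairs
    ]
    adjusted = bonferroni_adjust([r.p_value for r in raw], m=len(pairs))
    pairwise = [
        {
            "order_1": o1,
            "order_2": o2,
            "u": r.u_statistic,
            "p": r.p_value,
            "p_adjusted": p_adj,
        }
        for (o1, o2), r, p_adj in zip(pairs, raw, adjusted)
    ]
    verdict = "signal" if any(p < alpha for p in adjusted) else "no signal"
    return PhyloScreenResult(
        verdict=verdict,
        summaries=summaries,
        pairwise=pairwise,
        untested_orders=untested,
        alpha=alpha,
    )
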