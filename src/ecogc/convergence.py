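"""Cross-variable convergence: does one group top every trait dataset?

Given k independent trait datasets partitioned into the same g groups,
the observed statistic is whether a single group attains the highest
median in all k datasets.  Under exchangeability and independence across
variables the chance of a prespecified group doing so is (1/g)^k, and of
any one group doing so is g*(1/g)^k.  A label-permutation test (group
labels shuffled independently within each variable, preserving group
sizes) provides an empirical check that does not assume equal group
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TopGroup",
    "ConvergenceResult",
    "top_group",
    "exact_convergence_p",
    "permutation_convergence_p",
    "run_convergence",
]


@dataclass(frozen=True)
class TopGroup:
    """Arg-max-median group of one dataset; ties mean no winner."""

    label: str | None
    medians: dict
    tied: bool


def top_group(groups: Mapping[str, Sequence[float]]) -> TopGroup:
    """Group with the largest median; a tie at the top yields no winner."""
    if not groups:
        raise ValueError("no groups given")
    medians = {}
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {label!r} is empty")
        medians[label] = float(np.median(vals))
    top = max(medians.values())
    winners = [lab for lab, med in medians.items() if med == top]
    if len(winners) > 1:
        return TopGroup(label=None, medians=medians, tied=True)
    return TopGroup(label=winners[0], medians=medians, tied=False)


def exact_convergence_p(g: int, k: int, focal: str = "prespecified") -> float:
    """Closed-form convergence probability under exchangeability.

    ``focal="prespecified"``: one named group tops all k variables,
    (1/g)^k.  ``focal="any"``: some single group tops all k, g*(1/g)^k.
    """
    if g < 2:
        raise ValueError("need at least 2 groups")
    if k < 1:
        raise ValueError("need at least 1 variable")
    p = (1.0 / g) ** k
    if focal == "prespecified":
        return p
    if focal == "any":
        return g * p
    raise ValueError(f"unknown focal mode {focal!r}")


def _winner_matrix(
    groups: Mapping[str, Sequence[float]],
    labels: list[str],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-permutation winner index for one variable; -1 marks a tie."""
    sizes = [len(groups[lab]) for lab in labels]
    values = np.concatenate([np.asarray(groups[lab], dtype=float) for lab in labels])
    perm = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    bounds = np.cumsum([0] + sizes)
    medians = np.column_stack(
        [np.median(perm[:, bounds[i]:bounds[i + 1]], axis=1) for i in range(len(sizes))]
    )
    top = medians.max(axis=1, keepdims=True)
    is_top = medians == top
    winner = np.argmax(is_top, axis=1)
    winner[is_top.sum(axis=1) > 1] = -1
    return winner


def permutation_convergence_p(
    datasets: Sequence[Mapping[str, Sequence[float]]],
    n_perm: int,
    seed: int | None = None,
    focal_group: str | None = None,
) -> float:
    """Permutation estimate of the convergence p-value.

    Labels are shuffled independently within each variable, preserving
    group sizes.  With ``focal_group`` set, counts permutations in which
    that group tops every variable; otherwise counts permutations in
    which any single group tops every variable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = sorted(datasets[0])
    for ds in datasets:
        if sorted(ds) != labels:
            raise ValueError("all datasets must share the same group labels")
    rng = np.random.default_rng(seed)
    winners = np.column_stack(
        [_winner_matrix(ds, labels, n_perm, rng) for ds in datasets]
    )
    if focal_group is not None:
        idx = labels.index(focal_group)
        hits = np.all(winners == idx, axis=1)
    else:
        hits = (winners[:, 0] >= 0) & np.all(
            winners == winners[:, [0]], axis=1
        )
    return float(np.mean(hits))


@dataclass
class ConvergenceResult:
    observed_top: dict          # variable -> winning group label (or None)
    all_match: bool
    focal_group: str | None
    p_exact_prespecified: float
    p_exact_any: float
    p_permutation: float | None
    n_permutations: int


def run_convergence(
    datasets: Mapping[str, Mapping[str, Sequence[float]]],
    focal_group: str | None = "SWM",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ConvergenceResult:
    """Full convergence report across named variables.

    ``datasets`` maps variable name -> (group label -> values).
    ``all_match`` is True when every variable's top group equals
    ``focal_group`` (or, with no focal group, when all tops agree on a
    single untied winner).  Both closed forms and (for n_perm >= 1) the
    permutation estimate are reported; none is privileged.
    """
    tops = {var: top_group(groups) for var, groups in datasets.items()}
    observed = {var: t.label for var, t in tops.items()}
    labels_list = list(observed.values())
    if focal_group is not None:
        all_match = all(lab == focal_group for lab in labels_list)
    else:
        all_match = (
            labels_list[0] is not None
            and all(lab == labels_list[0] for lab in labels_list)
        )
    g = len(next(iter(datasets.values())))
    k = len(datasets)
    p_pre = exact_convergence_p(g, k, "prespecified")
    p_any = exact_convergence_p(g, k, "any")
    p_perm = None
    if n_perm >= 1:
        p_perm = permutation_convergence_p(
            list(datasets.values()), n_perm=n_perm, seed=seed, focal_group=focal_group
        )
    return ConvergenceResult(
        observed_top=observed,
        all_match=all_match,
        focal_group=focal_group,
        p_exact_prespecified=p_pre,
        p_exact_any=p_any,
        p_permutation=p_perm,
        n_permutations=n_perm if p_perm is not None else 0,
    )
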