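"""Independent brute-force oracles used to check the package's statistics.

These deliberately avoid the code paths they validate: the Mann-Whitney
oracle enumerates every labeling, and the ANOVA oracle fits nested
dummy-coded least-squares models with numpy only.
"""

from __future__ import annotations

import itertools

import numpy as np


def mw_u(a, b) -> float:
    """U statistic of sample a via direct pair counting (midranks via 0.5)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_p(a, b, alternative: str = "two_sided") -> float:
    """Exact Mann-Whitney p by enumerating all C(n1+n2, n1) labelings."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = mw_u(a, b)
    n1n2 = n1 * len(b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = set(idx)
        aa = [pooled[i] for i in sel]
        bb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(mw_u(aa, bb))
    us = np.array(us)
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    if alternative == "less":
        return float(np.mean(us <= u_obs))
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    return float(np.mean((us <= lo) | (us >= hi)))


def _dummy_design(a, b, terms):
    """Treatment-coded design matrix for the requested model terms."""
    a = np.asarray(a)
    b = np.asarray(b)
    cols = [np.ones(a.size)]
    ai = (a == sorted(set(a))[-1]).astype(float)
    bi = (b == sorted(set(b))[-1]).astype(float)
    if "A" in terms:
        cols.append(ai)
    if "B" in terms:
        cols.append(bi)
    if "AB" in terms:
        cols.append(ai * bi)
    return np.column_stack(cols)


def _rss(y, X) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_f_nested_ls(y, a, b, ss_type: str = "II"):
    """Two-way ANOVA F statistics by nested least-squares model comparison.

    Treatment coding is used for Types I and II (order-invariant /
    sequential SS do not depend on the coding); Type III uses
    sum-to-zero coding as required for its hypotheses.
    """
    y = np.asarray(y, dtype=float)

    def rss(terms, sum_code=False):
        if not sum_code:
            return _rss(y, _dummy_design(a, b, terms))
        ai = np.where(np.asarray(a) == sorted(set(a))[-1], 1.0, -1.0)
        bi = np.where(np.asarray(b) == sorted(set(b))[-1], 1.0, -1.0)
        cols = [np.ones(y.size)]
        if "A" in terms:
            cols.append(ai)
        if "B" in terms:
            cols.append(bi)
        if "AB" in terms:
            cols.append(ai * bi)
        return _rss(y, np.column_stack(cols))

    full = rss(("A", "B", "AB"))
    n = y.size
    df_err = n - np.linalg.matrix_rank(_dummy_design(a, b, ("A", "B", "AB")))
    ms_err = full / df_err
    if ss_type == "I":
        ss = (
            rss(()) - rss(("A",)),
            rss(("A",)) - rss(("A", "B")),
            rss(("A", "B")) - full,
        )
    elif ss_type == "II":
        ss = (
            rss(("B",)) - rss(("A", "B")),
            rss(("A",)) - rss(("A", "B")),
            rss(("A", "B")) - full,
        )
    elif ss_type == "III":
        full3 = rss(("A", "B", "AB"), sum_code=True)
        ss = (
            rss(("B", "AB"), sum_code=True) - full3,
            rss(("A", "AB"), sum_code=True) - full3,
            rss(("A", "B"), sum_code=True) - full3,
        )
    else:
        raise ValueError(ss_type)
    return tuple(s / ms_err for s in ss)
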