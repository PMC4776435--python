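"""Two-way factorial ANOVA with bootstrap assessment of the F statistics.

The design is salinity (FW/SW) by migration (NM/M), typically unbalanced.
Sums of squares are computed by nested least-squares model comparison
with sum-to-zero factor coding, supporting Type I (sequential), Type II
(default; each main effect adjusted for the other, interaction last) and
Type III (each term adjusted for all others).

Significance is assessed nonparametrically: the response vector is
resampled with replacement from the pooled observed responses while the
factor labels stay fixed (a global exchangeability null), all three F
statistics are recomputed per resample, and

    p = #(resampled F > observed F) / #(valid resamples)

with strict inequality.  Degenerate resamples (zero error variance)
yield NaN and are excluded from both counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import orth

from .species_io import Migration, Salinity, TraitDataset, partition_groups

logger = logging.getLogger(__name__)

__all__ = [
    "FactorialDesign",
    "AnovaResult",
    "anova_f",
    "bootstrap_null",
    "bootstrap_pvalue",
    "run_two_way",
]

_DEGENERATE_RTOL = 1e-12


@dataclass
class FactorialDesign:
    """Response values with their two factor label vectors."""

    response: np.ndarray
    factor_a: np.ndarray  # "FW" / "SW"
    factor_b: np.ndarray  # "NM" / "M"

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.factor_a = np.asarray(self.factor_a, dtype=object)
        self.factor_b = np.asarray(self.factor_b, dtype=object)
        n = self.response.size
        if not (self.factor_a.size == n and self.factor_b.size == n):
            raise ValueError("response and factor vectors must share one length")
        bad_a = set(self.factor_a) - {s.value for s in Salinity}
        bad_b = set(self.factor_b) - {m.value for m in Migration}
        if bad_a or bad_b:
            raise ValueError(f"unknown factor levels: {bad_a | bad_b}")

    @classmethod
    def from_groups(cls, cells: dict[str, Sequence[float]]) -> "FactorialDesign":
        """Build from a four-way partition mapping FWNM/FWM/SWNM/SWM -> values."""
        ys, fa, fb = [], [], []
        for label, vals in cells.items():
            sal, mig = label[:2], label[2:]
            for v in vals:
                ys.append(v)
                fa.append(sal)
                fb.append(mig)
        return cls(np.array(ys, dtype=float), np.array(fa), np.array(fb))

    def cell_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sal in ("FW", "SW"):
            for mig in ("NM", "M"):
                counts[sal + mig] = int(
                    np.sum((self.factor_a == sal) & (self.factor_b == mig))
                )
        return counts


@dataclass
class AnovaResult:
    f_a: float
    f_b: float
    f_ab: float
    df: dict
    ss_type: str
    b_resamples: int
    null_f_a: np.ndarray
    null_f_b: np.ndarray
    null_f_ab: np.ndarray
    p_a: float
    p_b: float
    p_ab: float
    seed: int | None = None
    excluded: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


class _ProjectorSet:
    """Orthonormal column bases for every model needed by one SS type.

    With the bases precomputed, the residual sum of squares of model M is
    ``y.y - |Q_M' y|^2``, so each bootstrap resample costs a handful of
    mat-vecs.  Rank-deficient designs (empty cells) are handled by
    ``scipy.linalg.orth``, which drops dependent columns.
    """

    def __init__(self, design: FactorialDesign, ss_type: str):
        a = np.where(design.factor_a == "SW", 1.0, -1.0)  # sum-to-zero coding
        b = np.where(design.factor_b == "M", 1.0, -1.0)
        one = np.ones_like(a)
        cols = {"1": one, "A": a, "B": b, "AB": a * b}

        def basis(terms: tuple[str, ...]) -> np.ndarray:
            X = np.column_stack([cols[t] for t in terms])
            return orth(X)

        models = {
            "1": ("1",),
            "A": ("1", "A"),
            "B": ("1", "B"),
            "A+B": ("1", "A", "B"),
            "B+AB": ("1", "B", "AB"),
            "A+AB": ("1", "A", "AB"),
            "full": ("1", "A", "B", "AB"),
        }
        self.q = {name: basis(terms) for name, terms in models.items()}
        self.rank = {name: q.shape[1] for name, q in self.q.items()}
        self.n = design.response.size
        self.ss_type = ss_type
        # (reduced, augmented) model pair per effect
        if ss_type == "I":
            self.pairs = {"a": ("1", "A"), "b": ("A", "A+B"), "ab": ("A+B", "full")}
        elif ss_type == "II":
            self.pairs = {"a": ("B", "A+B"), "b": ("A", "A+B"), "ab": ("A+B", "full")}
        elif ss_type == "III":
            self.pairs = {
                "a": ("B+AB", "full"),
                "b": ("A+AB", "full"),
                "ab": ("A+B", "full"),
            }
        else:
            raise ValueError(f"unknown SS type {ss_type!r}")
        self.df_err = self.n - self.rank["full"]
        self.df = {
            eff: self.rank[aug] - self.rank[red]
            for eff, (red, aug) in self.pairs.items()
        }

    def f_stats(self, Y: np.ndarray) -> np.ndarray:
        """F statistics for response matrix Y of shape (n, m): returns (3, m)."""
        Y = np.atleast_2d(Y.T).T  # ensure 2-D with columns = responses
        total = np.einsum("ij,ij->j", Y, Y)
        rss = {
            name: total - np.einsum("ij,ij->j", qty, qty)
            for name, qty in ((name, q.T @ Y) for name, q in self.q.items())
        }
        rss_err = rss["full"]
        scale = np.maximum(total, 1.0)
        out = np.full((3, Y.shape[1]), np.nan)
        if self.df_err < 1:
            return out
        ms_err = rss_err / self.df_err
        degenerate = rss_err <= _DEGENERATE_RTOL * scale
        for i, eff in enumerate(("a", "b", "ab")):
            red, aug = self.pairs[eff]
            df = self.df[eff]
            if df < 1:
                continue  # effect not estimable (e.g. empty cell)
            ss = np.maximum(rss[red] - rss[aug], 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss / df) / ms_err
            f[degenerate] = np.nan
            out[i] = f
        return out


def anova_f(
    design: FactorialDesign, ss_type: str = "II"
) -> tuple[float, float, float, dict]:
    """Observed F statistics (salinity, migration, interaction) and df.

    Returns NaN for an effect whose F is undefined: zero error variance
    (all responses identical within cells) or a non-estimable interaction
    (empty cell).  An empty cell with Type III sums of squares is an
    error, since the Type III main-effect hypotheses are not estimable.
    """
    counts = design.cell_counts()
    if ss_type == "III" and any(c == 0 for c in counts.values()):
        raise ValueError(
            f"empty cell(s) {[k for k, c in counts.items() if c == 0]} "
            "with Type III sums of squares"
        )
    proj = _ProjectorSet(design, ss_type)
    if proj.df_err < 1:
        raise ValueError("design leaves no error degrees of freedom")
    fs = proj.f_stats(design.response[:, None])[:, 0]
    if np.isnan(fs).any():
        logger.warning("undefined F statistic(s): %s", fs)
    df = {
        "a": (proj.df["a"], proj.df_err),
        "b": (proj.df["b"], proj.df_err),
        "ab": (proj.df["ab"], proj.df_err),
    }
    return float(fs[0]), float(fs[1]), float(fs[2]), df


def bootstrap_null(
    design: FactorialDesign,
    b: int = 1000,
    seed: int | None = None,
    ss_type: str = "II",
    scheme: str = "pooled",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap null distributions of the three F statistics.

    scheme="pooled" (default): each resample draws the whole response
    vector with replacement from the pooled observed responses, factor
    labels fixed — the global exchangeability null.

    scheme="residual": per effect, full-model residuals are resampled
    with replacement and added onto that effect's null-model fit.

    Degenerate resamples are returned as NaN.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(seed)
    proj = _ProjectorSet(design, ss_type)
    y = design.response
    n = y.size

    if scheme == "pooled":
        Y = rng.choice(y, size=(n, b), replace=True)
        fs = proj.f_stats(Y)
        return fs[0], fs[1], fs[2]
    if scheme == "residual":
        q_full = proj.q["full"]
        resid = y - q_full @ (q_full.T @ y)
        out = []
        for i, eff in enumerate(("a", "b", "ab")):
            red, _ = proj.pairs[eff]
            q_red = proj.q[red]
            fit_null = q_red @ (q_red.T @ y)
            R = rng.choice(resid, size=(n, b), replace=True)
            out.append(proj.f_stats(fit_null[:, None] + R)[i])
        return out[0], out[1], out[2]
    raise ValueError(f"unknown bootstrap scheme {scheme!r}")


def bootstrap_pvalue(
    observed_f: float, null_f: Sequence[float], plus_one: bool = False
) -> float:
    """p = #(null F strictly greater than observed F) / #(valid null F).

    NaN entries of the null (degenerate resamples) are excluded from both
    counts.  ``plus_one=True`` applies the (r+1)/(B+1) correction instead.
    A p of exactly 0 should be read as "< 1/B".
    """
    null_f = np.asarray(null_f, dtype=float)
    valid = null_f[~np.isnan(null_f)]
    if valid.size == 0:
        raise ValueError("no valid bootstrap F values")
    if np.isnan(observed_f):
        return float("nan")
    r = int(np.sum(valid > observed_f))
    if plus_one:
        return (r + 1) / (valid.size + 1)
    return r / valid.size


def run_two_way(
    dataset: TraitDataset,
    b: int = 1000,
    seed: int | None = None,
    ss_type: str = "II",
    scheme: str = "pooled",
) -> AnovaResult:
    """Classify, assemble the 2x2 design and run the full bootstrap ANOVA."""
    cells = partition_groups(dataset, mode="four_way")
    design = FactorialDesign.from_groups(cells)
    notes = []
    empty = [k for k, c in design.cell_counts().items() if c == 0]
    if empty:
        notes.append(f"empty cell(s) {empty}: interaction not estimable")
        logger.warning("%s", notes[-1])

    f_a, f_b, f_ab, df = anova_f(design, ss_type=ss_type)
    null_a, null_b, null_ab = bootstrap_null(
        design, b=b, seed=seed, ss_type=ss_type, scheme=scheme
    )

    def pval(obs: float, null: np.ndarray, name: str) -> float:
        if np.isnan(obs):
            notes.append(f"effect {name}: observed F undefined, p not computed")
            return float("nan")
        p = bootstrap_pvalue(obs, null)
        if p == 0.0:
            notes.append(f"effect {name}: p = 0, read as < 1/{b}")
        return p

    excluded = {
        "a": int(np.isnan(null_a).sum()),
        "b": int(np.isnan(null_b).sum()),
        "ab": int(np.isnan(null_ab).sum()),
    }
    result = AnovaResult(
        f_a=f_a,
        f_b=f_b,
        f_ab=f_ab,
        df=df,
        ss_type=ss_type,
        b_resamples=b,
        null_f_a=null_a,
        null_f_b=null_b,
        null_f_ab=null_ab,
        p_a=pval(f_a, null_a, "salinity"),
        p_b=pval(f_b, null_b, "migration"),
        p_ab=pval(f_ab, null_ab, "interaction"),
        seed=seed,
        excluded=excluded,
        notes=notes,
    )
    return result
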