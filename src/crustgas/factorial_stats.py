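"""Statistics for the balanced 2x2x2 microcosm experiment.

The design crosses wetting (flooded/wet-drained), light (light/dark) and
headspace (anoxic/oxic) with equal replication per cell, so the fixed-effects
least-squares decomposition is orthogonal: every term's sum of squares is a
single ±1 contrast on cell totals, and sequential and marginal sums of
squares coincide (the type-I/type-III distinction is moot). Rates and copy
numbers are log transformed before analysis. Welch t-tests and Pearson
correlations cover the pairwise comparisons reported alongside the ANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedCorrelationError, UnsupportedDesignError

__all__ = [
    "FactorialDataset",
    "FACTORS",
    "log_transform",
    "factorial_anova",
    "welch_t_test",
    "pearson_correlation",
]

FACTORS = ("wetting", "light", "headspace")
_LEVELS = {"wetting": ("F", "W"), "light": ("L", "D"), "headspace": ("N", "O")}


@dataclass
class FactorialDataset:
    """Responses with the three factor levels per observation.

    The ANOVA requires the full balanced design: all 8 cells present with the
    same number of replicates (n >= 2).
    """

    responses: np.ndarray
    wetting: np.ndarray  # 'F' or 'W'
    light: np.ndarray  # 'L' or 'D'
    headspace: np.ndarray  # 'N' or 'O'

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.wetting = np.asarray(self.wetting, dtype=object)
        self.light = np.asarray(self.light, dtype=object)
        self.headspace = np.asarray(self.headspace, dtype=object)
        n = self.responses.size
        for name in FACTORS:
            arr = getattr(self, name)
            if arr.size != n:
                raise InvalidInputError(f"factor {name} length differs from responses")
            bad = set(arr.tolist()) - set(_LEVELS[name])
            if bad:
                raise InvalidInputError(f"unknown {name} levels: {sorted(bad)}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str) -> "FactorialDataset":
        return cls(
            responses=df[response].to_numpy(dtype=float),
            wetting=df["wetting"].to_numpy(),
            light=df["light"].to_numpy(),
            headspace=df["headspace"].to_numpy(),
        )

    def cell_counts(self) -> dict[tuple[str, str, str], int]:
        counts: dict[tuple[str, str, str], int] = {}
        for w, l, h in zip(self.wetting, self.light, self.headspace):
            counts[(w, l, h)] = counts.get((w, l, h), 0) + 1
        return counts


def log_transform(values: Sequence[float], base: str = "natural") -> np.ndarray:
    """Elementwise log of strictly positive responses.

    ``base`` is ``"natural"`` (rates) or ``"log10"`` (copy numbers, reported
    as powers of ten). Non-positive entries abort with the offending indices.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        raise InvalidInputError(f"log transform requires positive values; offending rows: {bad.tolist()}")
    if base == "natural":
        return np.log(arr)
    if base == "log10":
        return np.log10(arr)
    raise InvalidInputError(f"unknown log base {base!r}")


def factorial_anova(data: FactorialDataset) -> pd.DataFrame:
    """Three-way fixed-effects ANOVA for the balanced 2x2x2 design.

    Each of the 7 terms (3 main effects, 3 two-way and 1 three-way
    interaction) has df = 1 and sum of squares ``(contrast of cell totals)^2
    / N`` with the orthogonal ±1 contrast of the involved factors;
    F = MS_term / MS_residual on (1, 8(n−1)) df. Returns a table indexed by
    term with columns sum_sq, df, mean_sq, F, p, plus Residual and Total rows.
    """
    counts = data.cell_counts()
    cells = list(itertools.product(*(_LEVELS[f] for f in FACTORS)))
    if set(counts) != set(cells):
        raise UnsupportedDesignError("all 8 factor-level cells must be present")
    ns = set(counts.values())
    if len(ns) != 1:
        raise UnsupportedDesignError(f"unbalanced design: cell counts {sorted(ns)}")
    n = ns.pop()
    if n < 2:
        raise UnsupportedDesignError("need at least 2 replicates per cell")
    big_n = 8 * n

    totals = {cell: 0.0 for cell in cells}
    for y, w, l, h in zip(data.responses, data.wetting, data.light, data.headspace):
        totals[(w, l, h)] += y
    grand = float(data.responses.sum())
    ss_total = float((data.responses**2).sum()) - grand**2 / big_n

    # ±1 coding: first level of each factor -> +1, second -> -1
    sign = {f: {_LEVELS[f][0]: 1.0, _LEVELS[f][1]: -1.0} for f in FACTORS}
    terms = [
        ("wetting",),
        ("light",),
        ("headspace",),
        ("wetting", "light"),
        ("wetting", "headspace"),
        ("light", "headspace"),
        ("wetting", "light", "headspace"),
    ]
    rows = []
    ss_model = 0.0
    for term in terms:
        contrast = 0.0
        for cell in cells:
            c = 1.0
            for f, level in zip(FACTORS, cell):
                if f in term:
                    c *= sign[f][level]
            contrast += c * totals[cell]
        ss = contrast**2 / big_n
        ss_model += ss
        rows.append({"term": ":".join(term), "sum_sq": ss, "df": 1})

    ss_resid = max(ss_total - ss_model, 0.0)
    df_resid = 8 * (n - 1)
    ms_resid = ss_resid / df_resid
    for row in rows:
        row["mean_sq"] = row["sum_sq"] / row["df"]
        if ms_resid > 0:
            row["F"] = row["mean_sq"] / ms_resid
            row["p"] = float(stats.f.sf(row["F"], row["df"], df_resid))
        else:
            # zero residual variance: any nonzero effect is infinitely significant
            row["F"] = math.inf if row["sum_sq"] > 0 else 0.0
            row["p"] = 0.0 if row["sum_sq"] > 0 else 1.0
    rows.append(
        {
            "term": "Residual",
            "sum_sq": ss_resid,
            "df": df_resid,
            "mean_sq": ms_resid,
            "F": math.nan,
            "p": math.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "sum_sq": ss_total,
            "df": big_n - 1,
            "mean_sq": math.nan,
            "F": math.nan,
            "p": math.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df, two-sided p).

    Degenerate zero-variance inputs are resolved by the means: equal means
    give (0, df, 1), separated means give (inf, df, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(res.df) if hasattr(res, "df") else float("nan")
    return float(res.statistic), df, float(res.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided p (t transform, n−2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise InvalidInputError("need paired samples with n >= 3")
    if xa.var() == 0.0 or ya.var() == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
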