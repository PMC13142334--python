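"""Group statistics and comparison reporting.

Implements the tests used for the tissue-level comparisons: two-sided
Student's and Welch's t-tests, Benjamini-Hochberg correction, balanced
two-way ANOVA with Tukey HSD on cell means, and the fold-change / delta
report for treated-vs-control group means.  The t statistic and the ANOVA
sums of squares are computed from the textbook formulas directly (scipy
and statsmodels serve as independent cross-checks in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ttest_two_sided", "bh_adjust", "anova2_tukey", "fold_change_report",
    "TwoWayAnovaResult", "TukeyComparison",
]


def ttest_two_sided(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance or Welch.

    Returns ``(t, p)``.  Identical groups give ``(0.0, 1.0)``.  Requires
    at least 2 observations per group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    if welch:
        se2 = va / na + vb / nb
        t = diff / math.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TukeyComparison:
    """One pairwise cell-mean comparison from Tukey's HSD."""

    cell_a: tuple[str, str]
    cell_b: tuple[str, str]
    mean_diff: float
    q_statistic: float
    p_value: float


@dataclass
class TwoWayAnovaResult:
    """Balanced two-way ANOVA decomposition with Tukey HSD follow-up."""

    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    cell_means: pd.DataFrame
    tukey: list[TukeyComparison] = field(default_factory=list)
    degenerate: bool = False     # zero residual variance


def anova2_tukey(table: pd.DataFrame, value: str = "value",
                 factor_a: str = "condition",
                 factor_b: str = "genotype") -> TwoWayAnovaResult:
    """Balanced two-way ANOVA (A x B) with Tukey HSD on the cell means.

    The design must be balanced with every cell filled (the offending cell
    is named otherwise).  Sums of squares follow the textbook balanced
    decomposition, so ``SS_total = SS_A + SS_B + SS_AB + SS_error`` holds
    to machine precision.  Tukey comparisons use the studentized range
    with the residual degrees of freedom, comparing all pairs of cells
    (simple effects included).
    """
    df = table[[value, factor_a, factor_b]].dropna()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index or counts[(la, lb)] == 0:
                raise ValueError(f"empty cell ({factor_a}={la}, {factor_b}={lb})")
    if counts.nunique() != 1:
        raise ValueError("design is unbalanced: unequal cell sizes "
                         f"{dict(counts)}")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need >= 2 observations per cell")
    a, b = len(levels_a), len(levels_b)

    y = df[value].astype(float)
    grand = y.mean()
    mean_a = df.groupby(factor_a, observed=True)[value].mean()
    mean_b = df.groupby(factor_b, observed=True)[value].mean()
    mean_ab = df.groupby([factor_a, factor_b], observed=True)[value].mean()

    ss_a = n * b * float(((mean_a - grand) ** 2).sum())
    ss_b = n * a * float(((mean_b - grand) ** 2).sum())
    ss_cells = n * float(((mean_ab - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    resid = y - df.set_index([factor_a, factor_b]).index.map(mean_ab).values
    ss_err = float((resid ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())

    dfs = {"A": a - 1, "B": b - 1, "AB": (a - 1) * (b - 1),
           "error": a * b * (n - 1), "total": a * b * n - 1}
    sss = {"A": ss_a, "B": ss_b, "AB": ss_ab, "error": ss_err, "total": ss_tot}
    ms = {k: sss[k] / dfs[k] if dfs[k] > 0 else math.nan
          for k in ("A", "B", "AB", "error")}
    degenerate = ms["error"] == 0
    fstat, pval = {}, {}
    for k in ("A", "B", "AB"):
        if degenerate:
            fstat[k] = math.inf if sss[k] > 0 else math.nan
            pval[k] = 0.0 if sss[k] > 0 else math.nan
        else:
            fstat[k] = ms[k] / ms["error"]
            pval[k] = float(stats.f.sf(fstat[k], dfs[k], dfs["error"]))

    cell_means = mean_ab.rename("mean").reset_index()
    tukey: list[TukeyComparison] = []
    if not degenerate:
        k_cells = a * b
        se = math.sqrt(ms["error"] / n)
        cells = list(mean_ab.index)
        for ca, cb in combinations(cells, 2):
            diff = float(mean_ab[ca] - mean_ab[cb])
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k_cells, dfs["error"]))
            tukey.append(TukeyComparison(cell_a=ca, cell_b=cb, mean_diff=diff,
                                         q_statistic=q, p_value=min(p, 1.0)))
    return TwoWayAnovaResult(ss=sss, df=dfs, ms=ms, f=fstat, p=pval,
                             cell_means=cell_means, tukey=tukey,
                             degenerate=degenerate)


def fold_change_report(means: pd.DataFrame, control: str = "control",
                       treated: str = "treated",
                       delta_scale: float = 1.0) -> pd.DataFrame:
    """Treated-vs-control ratios and deltas per measurement and group.

    ``means`` has one row per (measurement, group) with columns named by
    ``control`` and ``treated`` holding the two group means.  Adds:

    * ``ratio`` — treated / control at full precision;
    * ``ratio_1dp`` — rounded to 1 decimal, mirroring "1.6-fold" style
      reporting;
    * ``delta`` — (treated - control) * ``delta_scale`` (e.g. 1000 to
      report seconds as ms).
    """
    out = means.copy()
    out["ratio"] = out[treated] / out[control]
    out["ratio_1dp"] = out["ratio"].round(1)
    out["delta"] = (out[treated] - out[control]) * delta_scale
    return out
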