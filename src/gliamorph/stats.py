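"""Group statistics on per-animal aggregated measurements.

The statistical unit is the animal: per-cell measurements are averaged per
animal before any test, matching study designs where "each point represents
one animal".  Two-group comparisons use the unpaired two-sided Student
t-test (equal variances pooled; Welch available by flag); 2×2 designs use a
two-way ANOVA with Type-II sums of squares followed by Tukey's HSD on the
four cell means with the studentized-range distribution (harmonic-mean cell
size when unbalanced).  Significance stars follow the thresholds
*p<0.05, **p<0.005, ***p<0.0005.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

STAR_THRESHOLDS = (0.05, 0.005, 0.0005)

FACTOR_COLUMNS = ("region", "age", "diet", "treatment")


def significance_stars(p: float) -> str:
    """'*' for p<0.05, '**' for p<0.005, '***' for p<0.0005, else ''."""
    n = sum(p < t for t in STAR_THRESHOLDS)
    return "*" * n


def percent_change(mean_a: float, mean_b: float) -> float:
    """100 × (mean_B − mean_A) / mean_A on per-animal group means."""
    return float(100.0 * (mean_b - mean_a) / mean_a)


def aggregate(per_cell: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Collapse a tidy per-cell table to one row per animal × metric.

    Expects columns ``animal_id``, ``metric``, ``value`` and any subset of
    the factor columns (region/age/diet/treatment).  The per-animal value is
    the arithmetic mean over that animal's cells; animals with no cells for
    a metric simply have no row (logged).
    """
    if "animal_id" not in per_cell.columns:
        raise ValueError("per-cell table must carry an animal_id column")
    keys = ["animal_id", "metric"] + [c for c in FACTOR_COLUMNS if c in per_cell.columns]
    n_in = per_cell.groupby(keys, dropna=False, observed=True)
    out = n_in[value].mean().reset_index()
    n_cells = n_in[value].size().reset_index(name="n_cells")
    out = out.merge(n_cells, on=keys)
    return out


@dataclass
class ComparisonResult:
    design: str                       # "two_group" | "two_way"
    metric: str
    factors: tuple[str, ...]
    group_labels: list
    group_means: np.ndarray
    group_sems: np.ndarray
    group_ns: np.ndarray
    statistic: float                  # t (two_group) or interaction F (two_way)
    df: tuple
    p: float
    percent_change: float
    anova: Optional[pd.DataFrame] = None
    tukey: Optional[pd.DataFrame] = None
    note: str = ""


def _group_stats(groups: list[np.ndarray]):
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    sems = np.array([g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan for g in groups])
    return means, sems, ns


def two_group_test(
    table: pd.DataFrame,
    metric: str,
    factor: str,
    value: str = "value",
    equal_var: bool = True,
    levels: tuple | None = None,
) -> ComparisonResult:
    """Unpaired two-sided t-test between the two levels of ``factor``.

    ``levels`` fixes the (baseline, comparison) order for the sign of t and
    of the percent change; the default is alphabetical.  Degenerate
    zero-variance input is handled explicitly: equal group means give
    t = 0, p = 1; unequal means with zero pooled variance are flagged
    (p = 0, note set) rather than returning NaN.
    """
    sub = table[table["metric"] == metric] if "metric" in table.columns else table
    found = sorted(sub[factor].dropna().unique())
    if len(found) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {found}")
    if levels is None:
        levels = found
    elif sorted(levels) != found:
        raise ValueError(f"levels {levels} do not match the data levels {found}")
    groups = [sub.loc[sub[factor] == lv, value].to_numpy(dtype=float) for lv in levels]
    for lv, g in zip(levels, groups):
        if len(g) < 2:
            raise ValueError(f"group {lv!r} has n={len(g)} < 2")
    means, sems, ns = _group_stats(groups)

    note = ""
    pooled = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(pooled, 0.0):
        if np.isclose(means[0], means[1]):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf, 0.0
            note = "zero within-group variance with unequal means"
        df = ns.sum() - 2
    else:
        t, p = sps.ttest_ind(groups[1], groups[0], equal_var=equal_var)
        if equal_var:
            df = ns.sum() - 2
        else:
            v = [g.var(ddof=1) / len(g) for g in groups]
            df = (v[0] + v[1]) ** 2 / sum(
                vi**2 / (len(g) - 1) for vi, g in zip(v, groups)
            )
    return ComparisonResult(
        design="two_group",
        metric=metric,
        factors=(factor,),
        group_labels=list(levels),
        group_means=means,
        group_sems=sems,
        group_ns=ns,
        statistic=float(t),
        df=(float(df),),
        p=float(p),
        percent_change=percent_change(means[0], means[1]),
        note=note,
    )


def two_way_anova_tukey(
    table: pd.DataFrame,
    metric: str,
    factor_a: str,
    factor_b: str,
    value: str = "value",
    with_tukey: bool = True,
) -> ComparisonResult:
    """2×2 two-way ANOVA (Type-II SS) with Tukey HSD on the four cell means.

    Raises if either factor does not have exactly two levels or any design
    cell is empty (the offending cell is named).  The headline statistic is
    the interaction F; the full ANOVA table and pairwise Tukey p-values are
    attached.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = table[table["metric"] == metric] if "metric" in table.columns else table
    sub = sub.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    lv_a = sorted(sub["_fa"].dropna().unique())
    lv_b = sorted(sub["_fb"].dropna().unique())
    if len(lv_a) != 2 or len(lv_b) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    cells = {}
    for a in lv_a:
        for b in lv_b:
            g = sub.loc[(sub["_fa"] == a) & (sub["_fb"] == b), "_y"].to_numpy(dtype=float)
            if len(g) == 0:
                raise ValueError(f"empty design cell ({factor_a}={a}, {factor_b}={b})")
            cells[(a, b)] = g

    y = sub["_y"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        # constant response: all effects are exactly zero by convention
        anova = None
        f_int, p_int = 0.0, 1.0
        df_resid = float(len(y) - 4)
        mse = 0.0
    else:
        model = smf.ols("_y ~ C(_fa) * C(_fb)", data=sub).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        f_int = float(anova.loc["C(_fa):C(_fb)", "F"])
        p_int = float(anova.loc["C(_fa):C(_fb)", "PR(>F)"])
        df_resid = float(model.df_resid)
        mse = float(model.mse_resid)

    # Tukey HSD on the 4 cell means, harmonic-mean cell size when unbalanced
    labels = list(cells.keys())
    means, sems, ns = _group_stats([cells[k] for k in labels])
    tukey = None
    if with_tukey:
        n_h = len(labels) / np.sum(1.0 / ns)
        se = np.sqrt(mse / n_h)
        rows = []
        for (i, j) in combinations(range(len(labels)), 2):
            diff = means[j] - means[i]
            q = np.abs(diff) / se if se > 0 else (0.0 if np.isclose(diff, 0) else np.inf)
            p_adj = (
                float(sps.studentized_range.sf(q, len(labels), df_resid))
                if np.isfinite(q)
                else 0.0
            )
            rows.append(
                dict(group_a=str(labels[i]), group_b=str(labels[j]), diff=float(diff),
                     q=float(q), p_adj=min(1.0, p_adj))
            )
        tukey = pd.DataFrame(rows)

    # headline percent change: main effect of factor_a (level 2 vs level 1)
    ma = [sub.loc[sub["_fa"] == a, "_y"].mean() for a in lv_a]
    return ComparisonResult(
        design="two_way",
        metric=metric,
        factors=(factor_a, factor_b),
        group_labels=[f"{a}|{b}" for (a, b) in labels],
        group_means=means,
        group_sems=sems,
        group_ns=ns,
        statistic=f_int,
        df=(1.0, df_resid),
        p=p_int,
        percent_change=percent_change(ma[0], ma[1]),
        anova=anova,
        tukey=tukey,
    )


def report(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy summary of comparisons with means ± SEM, p and stars."""
    if not comparisons:
        raise ValueError("at least one comparison is required")
    rows = []
    for c in comparisons:
        for lbl, m, s, n in zip(c.group_labels, c.group_means, c.group_sems, c.group_ns):
            rows.append(
                dict(
                    metric=c.metric,
                    design=c.design,
                    factors="×".join(c.factors),
                    group=str(lbl),
                    mean=float(m),
                    sem=float(s),
                    n=int(n),
                    statistic=c.statistic,
                    p=c.p,
                    stars=significance_stars(c.p),
                    percent_change=c.percent_change,
                )
            )
    return pd.DataFrame(rows)
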