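"""Group statistics: closed-form oracles, degenerate inputs, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliamorph.stats import (
    aggregate,
    percent_change,
    report,
    significance_stars,
    two_group_test,
    two_way_anova_tukey,
)


def long_table(groups: dict, metric="length", factor="diet"):
    rows = []
    for level, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"animal_id": f"{level}_{i}", factor: level,
                         "metric": metric, "value": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_means_per_animal():
    per_cell = pd.DataFrame(
        dict(animal_id=["a1"] * 3, metric=["len"] * 3, value=[10.0, 20.0, 30.0])
    )
    out = aggregate(per_cell)
    assert len(out) == 1
    assert out.loc[0, "value"] == pytest.approx(20.0)
    assert out.loc[0, "n_cells"] == 3


def test_aggregate_two_animals_two_rows():
    per_cell = pd.DataFrame(
        dict(animal_id=["a1", "a1", "a2"], metric=["len"] * 3, value=[1.0, 3.0, 5.0])
    )
    out = aggregate(per_cell)
    assert len(out) == 2
    assert sorted(out["value"]) == [2.0, 5.0]


def test_per_animal_averaging_differs_from_pooling():
    """Unequal cells per animal: per-animal means weight animals equally,
    unlike naive per-cell pooling (regression fixture, hand-computed)."""
    per_cell = pd.DataFrame(
        dict(
            animal_id=["a1"] * 4 + ["a2"],
            metric=["len"] * 5,
            value=[10.0, 10.0, 10.0, 10.0, 30.0],
        )
    )
    out = aggregate(per_cell)
    group_mean = out["value"].mean()
    assert group_mean == pytest.approx(20.0)          # (10 + 30) / 2
    assert per_cell["value"].mean() == pytest.approx(14.0)  # pooled is different


def test_aggregate_requires_animal_id():
    with pytest.raises(ValueError):
        aggregate(pd.DataFrame(dict(metric=["x"], value=[1.0])))


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_identical_groups_t_zero_p_one():
    t = long_table({"A": [1, 2, 3], "B": [1, 2, 3]})
    res = two_group_test(t, "length", "diet")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert res.percent_change == pytest.approx(0.0, abs=1e-12)


def test_matches_textbook_pooled_formula():
    """t and p equal the explicit pooled-SD computation with df = 6."""
    a, b = [10.0, 12.0, 14.0, 16.0], [20.0, 22.0, 24.0, 26.0]
    res = two_group_test(long_table({"A": a, "B": b}), "length", "diet")
    # independent closed-form computation
    ma, mb = np.mean(a), np.mean(b)
    sp2 = (np.sum((a - ma) ** 2) + np.sum((b - mb) ** 2)) / 6.0
    t_expected = (mb - ma) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
    p_expected = 2 * sps.t.sf(abs(t_expected), 6)
    assert res.statistic == pytest.approx(t_expected, rel=1e-12)
    assert res.df[0] == 6
    assert res.p == pytest.approx(p_expected, rel=1e-12)


def test_zero_variance_handling():
    same = long_table({"A": [5.0, 5.0], "B": [5.0, 5.0]})
    res = two_group_test(same, "length", "diet")
    assert res.statistic == 0.0 and res.p == 1.0
    diff = long_table({"A": [5.0, 5.0], "B": [7.0, 7.0]})
    res2 = two_group_test(diff, "length", "diet")
    assert res2.p == 0.0 and res2.note != ""


def test_small_group_rejected():
    t = long_table({"A": [1.0], "B": [1.0, 2.0]})
    with pytest.raises(ValueError):
        two_group_test(t, "length", "diet")


def test_welch_flag_changes_df():
    t = long_table({"A": [1.0, 2.0, 3.0], "B": [10.0, 30.0, 50.0, 70.0]})
    pooled = two_group_test(t, "length", "diet")
    welch = two_group_test(t, "length", "diet", equal_var=False)
    assert pooled.df[0] == 5
    assert welch.df[0] != 5


# ---------------------------------------------------------------------------
# two-way ANOVA + Tukey
# ---------------------------------------------------------------------------

def two_way_table(cells: dict):
    rows = []
    for (a, b), values in cells.items():
        for i, v in enumerate(values):
            rows.append({"animal_id": f"{a}{b}{i}", "diet": a, "treatment": b,
                         "metric": "m", "value": float(v)})
    return pd.DataFrame(rows)


def test_identical_cells_give_null_anova():
    t = two_way_table({(a, b): [3.0, 3.0, 3.0] for a in "XY" for b in "UV"})
    res = two_way_anova_tukey(t, "m", "diet", "treatment")
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert np.all(res.tukey["p_adj"] >= 0.999)


def test_balanced_interaction_matches_hand_computed_sums_of_squares():
    """Balanced 2×2: interaction F equals the closed-form ANOVA formula."""
    cells = {
        ("X", "U"): [1.0, 2.0, 3.0],
        ("X", "V"): [2.0, 3.0, 4.0],
        ("Y", "U"): [5.0, 6.0, 7.0],
        ("Y", "V"): [6.0, 7.0, 9.0],
    }
    res = two_way_anova_tukey(two_way_table(cells), "m", "diet", "treatment")
    # hand computation (balanced: Type-II == Type-I == Type-III)
    data = {k: np.asarray(v) for k, v in cells.items()}
    n = 3
    grand = np.mean([v for vs in data.values() for v in vs])
    mean_a = {a: np.mean(np.concatenate([data[(a, b)] for b in "UV"])) for a in "XY"}
    mean_b = {b: np.mean(np.concatenate([data[(a, b)] for a in "XY"])) for b in "UV"}
    ss_int = n * sum(
        (data[(a, b)].mean() - mean_a[a] - mean_b[b] + grand) ** 2
        for a in "XY" for b in "UV"
    )
    ss_err = sum(np.sum((v - v.mean()) ** 2) for v in data.values())
    f_expected = (ss_int / 1.0) / (ss_err / 8.0)
    assert res.statistic == pytest.approx(f_expected, rel=1e-10)
    assert res.df == (1.0, 8.0)


def test_empty_cell_raises_naming_cell():
    cells = {("X", "U"): [1.0, 2.0], ("X", "V"): [2.0, 3.0], ("Y", "U"): [4.0, 5.0]}
    t = two_way_table(cells)
    with pytest.raises(ValueError, match="Y.*V"):
        two_way_anova_tukey(t, "m", "diet", "treatment")


def test_tukey_matches_statsmodels_on_balanced_design():
    """Cross-check: our studentized-range p-values equal statsmodels' Tukey
    HSD on a balanced design."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(4)
    cells = {(a, b): rng.normal(2.0 + (a == "Y") * 1.5, 1.0, 6)
             for a in "XY" for b in "UV"}
    t = two_way_table(cells)
    res = two_way_anova_tukey(t, "m", "diet", "treatment")
    combo = t["diet"] + "|" + t["treatment"]
    sm_res = pairwise_tukeyhsd(t["value"], combo)
    ours = res.tukey.sort_values(["group_a", "group_b"])["p_adj"].to_numpy()
    theirs = np.sort(sm_res.pvalues)
    assert np.allclose(np.sort(ours), theirs, atol=1e-6)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,stars", [(0.2, ""), (0.03, "*"), (0.004, "**"),
                                     (0.0004, "***"), (0.05, "")])
def test_significance_stars(p, stars):
    assert significance_stars(p) == stars


def test_percent_change_identity():
    assert percent_change(5.0, 5.0) == 0.0


def test_report_table():
    t = long_table({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]})
    res = two_group_test(t, "length", "diet")
    rep = report([res])
    assert set(rep["group"]) == {"A", "B"}
    assert {"mean", "sem", "n", "p", "stars", "percent_change"} <= set(rep.columns)
    with pytest.raises(ValueError):
        report([])
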