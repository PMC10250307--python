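"""Tests of the cohort-statistics engine against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octa_asym import errors
from octa_asym.stats import (
    association_test,
    categorical_association,
    compare_groups,
    correlate,
    dunn_posthoc,
    fisher_exact_2x2,
    fit_adjusted_regression,
)


def _table(groups):
    rows = [(g, v) for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows, columns=["group", "y"])


# ------------------------------------------------------------ omnibus tests

def test_kruskal_statistic_matches_hand_ranked_formula():
    """KW statistic agrees exactly with the brute-force rank computation
    H = (12/(N(N+1))) sum n_i (Rbar_i - Rbar)^2, tie-corrected."""
    groups = {
        "a": [1.2, 3.4, 2.2, 5.0, 4.1],
        "b": [2.2, 6.1, 5.5, 7.0, 6.6],
        "c": [0.5, 1.1, 2.0, 3.3, 2.2],
    }
    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    n_tot = len(pooled)
    grand = ranks.mean()
    h, i0 = 0.0, 0
    for vals in groups.values():
        r = ranks[i0 : i0 + len(vals)]
        h += len(vals) * (r.mean() - grand) ** 2
        i0 += len(vals)
    h *= 12.0 / (n_tot * (n_tot + 1))
    _, counts = np.unique(pooled, return_counts=True)
    h /= 1.0 - ((counts**3 - counts).sum()) / (n_tot**3 - n_tot)

    res = compare_groups(_table(groups), "y", method="kruskal")
    assert res.omnibus_stat == pytest.approx(h, abs=1e-12)


def test_two_group_kruskal_equals_mann_whitney():
    """With k = 2, the KW omnibus p equals the two-sided (tie-corrected,
    normal-approximated) Mann-Whitney p on the same data."""
    rng = np.random.default_rng(5)
    groups = {"a": rng.normal(0, 1, 18).round(1).tolist(),
              "b": rng.normal(0.7, 1, 22).round(1).tolist()}
    res = compare_groups(_table(groups), "y", method="kruskal")
    mw = sps.mannwhitneyu(groups["a"], groups["b"], alternative="two-sided",
                          method="asymptotic", use_continuity=False)
    assert res.omnibus_p == pytest.approx(mw.pvalue, rel=1e-9)


def test_auto_path_selection_records_decision():
    rng = np.random.default_rng(0)
    normal = {g: rng.normal(0, 1, 40) for g in "abcd"}
    res = compare_groups(_table(normal), "y")
    assert res.method == "anova+dunn-bonferroni"
    skewed = {g: rng.lognormal(0, 1.5, 40) ** 2 for g in "abcd"}
    res2 = compare_groups(_table(skewed), "y")
    assert res2.method == "kruskal+dunn"
    assert res2.normality_p <= 0.05 or res2.homogeneity_p <= 0.05


def test_shifted_group_flagged_in_posthoc_only():
    """One strongly shifted group: its three contrasts reject, the three
    contrasts among unshifted groups do not."""
    rng = np.random.default_rng(11)
    groups = {g: rng.normal(0, 1, 30) for g in "abc"}
    groups["d"] = rng.normal(8, 1, 30)
    res = compare_groups(_table(groups), "y")
    assert res.omnibus_p < 0.001
    for g1, g2 in itertools.combinations("abcd", 2):
        p = res.pairwise_p(g1, g2)
        if "d" in (g1, g2):
            assert p < 0.05
        else:
            assert p > 0.05


def test_compare_groups_invariant_to_label_permutation():
    rng = np.random.default_rng(2)
    groups = {g: rng.normal(i, 1, 15) for i, g in enumerate("abc")}
    res1 = compare_groups(_table(groups), "y", method="kruskal")
    rev = {g: groups[g] for g in reversed(list(groups))}
    res2 = compare_groups(_table(rev), "y", method="kruskal")
    assert res1.omnibus_stat == pytest.approx(res2.omnibus_stat)
    for (g1, g2), r in res1.pairwise.items():
        assert res2.pairwise_p(g1, g2) == pytest.approx(r["p_adj"])


def test_bonferroni_monotonicity():
    """Adjusted p-values are >= raw p-values and capped at 1."""
    rng = np.random.default_rng(4)
    groups = {g: rng.normal(0, 1, 12) for g in "abcd"}
    for res in dunn_posthoc(groups).values():
        assert res["p_adj"] >= res["p_raw"]
        assert res["p_adj"] <= 1.0


def test_compare_groups_error_contracts():
    with pytest.raises(errors.InsufficientDataError):
        compare_groups(_table({"a": [1.0], "b": [2.0, 3.0]}), "y")
    with pytest.raises(errors.DegenerateDataError):
        compare_groups(_table({"a": [2.0, 2.0], "b": [2.0, 2.0]}), "y")


# ------------------------------------------------------------- categoricals

def test_balanced_2x2_has_zero_statistic():
    res = association_test(np.array([[10, 10], [10, 10]]))
    assert res.method == "chi-squared"
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_low_expected_counts_switch_to_fisher():
    """[[8,2],[1,5]]: min expected count 6*7/16 = 2.625 < 5, so the exact
    path is taken; p equals the hypergeometric enumeration."""
    tab = np.array([[8, 2], [1, 5]])
    expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    assert expected.min() == pytest.approx(2.625)
    res = association_test(tab)
    assert res.method == "fisher"
    # enumeration oracle over all tables with the observed margins
    r1, c1, n = 10, 9, 16
    pmf = [sps.hypergeom.pmf(a, n, r1, c1)
           for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)]
    p_obs = sps.hypergeom.pmf(8, n, r1, c1)
    p_exact = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
    assert res.p == pytest.approx(p_exact, rel=1e-9)


def test_sex_by_group_association_from_printed_counts():
    """Female counts 30/72/15/7 of groups sized 60/132/40/26 show a
    significant sex-severity association (chi-squared path)."""
    females = [30, 72, 15, 7]
    totals = [60, 132, 40, 26]
    tab = np.array([females, [t - f for f, t in zip(females, totals)]])
    res = association_test(tab)
    assert res.method == "chi-squared"
    assert res.p < 0.05


def test_larger_table_with_small_counts_uses_mc_fisher():
    tab = np.array([[4, 1, 0], [0, 3, 2], [1, 0, 4]])
    res = association_test(tab, seed=1)
    assert res.method == "fisher-mc"
    assert 0.0 < res.p <= 1.0


def test_single_level_variable_is_degenerate():
    df = pd.DataFrame({"group": ["a", "a", "b", "b"], "v": [1, 1, 1, 1]})
    with pytest.raises(errors.DegenerateDataError):
        categorical_association(df, "v")


def test_fisher_helper_validates_shape():
    with pytest.raises(errors.ValidationError):
        fisher_exact_2x2(np.ones((2, 3)))


# ------------------------------------------------------------- correlation

def test_correlation_of_exact_line_is_one():
    df = pd.DataFrame({"x": np.arange(10.0)})
    df["y"] = 2 * df["x"] + 1
    res = correlate(df, "x", "y")
    assert res.r == pytest.approx(1.0)
    assert res.n == 10


def test_correlation_null_bound():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"x": rng.normal(size=500), "y": rng.normal(size=500)})
    assert abs(correlate(df, "x", "y").r) < 0.15


def test_correlation_uses_complete_cases_and_errors_when_few():
    df = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0],
                       "y": [2.0, np.nan, 3.0, 8.0]})
    with pytest.raises(errors.InsufficientDataError):
        correlate(df, "x", "y")  # only 2 complete cases


# -------------------------------------------------------------- regression

def test_noiseless_regression_recovers_slope_exactly():
    df = pd.DataFrame({"x": np.linspace(0, 10, 20)})
    df["y"] = 0.5 * df["x"] + 2.0
    res = fit_adjusted_regression(df, "y", "x")
    assert res.exposure_beta == pytest.approx(0.5, abs=1e-10)
    lo, hi = res.exposure_ci
    assert hi - lo == pytest.approx(0.0, abs=1e-8)


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(21)
    df = pd.DataFrame({
        "x": rng.normal(size=60),
        "z": rng.normal(size=60),
    })
    df["y"] = 1.0 + 0.8 * df["x"] - 0.3 * df["z"] + rng.normal(0, 0.5, 60)
    res = fit_adjusted_regression(df, "y", "x", adjustment=["z"])
    X = np.column_stack([np.ones(60), df["x"], df["z"]])
    beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
    assert res.coefficients.loc["const", "beta"] == pytest.approx(beta[0], abs=1e-8)
    assert res.exposure_beta == pytest.approx(beta[1], abs=1e-8)
    assert res.coefficients.loc["z", "beta"] == pytest.approx(beta[2], abs=1e-8)


def test_collinear_design_names_aliased_column():
    rng = np.random.default_rng(31)
    df = pd.DataFrame({"x": rng.normal(size=40)})
    df["x2"] = 2.0 * df["x"]
    df["y"] = df["x"] + rng.normal(size=40)
    with pytest.raises(errors.CollinearityError) as exc:
        fit_adjusted_regression(df, "y", "x", adjustment=["x2"])
    assert "x2" in exc.value.aliased


def test_categorical_coding_matches_contract():
    """Sex dummy (male=1), race dummies vs the largest level, DR grade as
    ordered 0-3 — checked against a hand-built design."""
    rng = np.random.default_rng(41)
    n = 120
    df = pd.DataFrame({
        "hba1c": rng.normal(8, 2, n),
        "sex": rng.choice(["F", "M"], n),
        "race": rng.choice(["Hispanic", "Asian", "Other"], n, p=[0.6, 0.2, 0.2]),
        "group": rng.choice(["no DM", "DM without DR", "NPDR", "PDR"], n),
    })
    df["y"] = (0.3 * df["hba1c"] + 1.0 * (df["sex"] == "M")
               + rng.normal(0, 0.1, n))
    res = fit_adjusted_regression(df, "y", "hba1c",
                                  adjustment=["sex", "race", "group"])
    terms = set(res.coefficients.index)
    assert {"hba1c", "sex", "dr_grade"} <= terms
    assert "race[Hispanic]" not in terms      # reference = largest level
    assert {"race[Asian]", "race[Other]"} <= terms
    assert res.coefficients.loc["sex", "beta"] == pytest.approx(1.0, abs=0.1)


def test_permuted_exposure_null_rejection_rate():
    """With the exposure permuted, the exposure p-value rejects at ~5%."""
    rng = np.random.default_rng(51)
    n, reps, rej = 80, 250, 0
    base_x = rng.normal(size=n)
    for _ in range(reps):
        df = pd.DataFrame({"x": rng.permutation(base_x),
                           "y": rng.normal(size=n)})
        res = fit_adjusted_regression(df, "y", "x")
        rej += res.exposure_p < 0.05
    assert 0.01 <= rej / reps <= 0.10


def test_regression_insufficient_data():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
    with pytest.raises(errors.InsufficientDataError):
        fit_adjusted_regression(df, "y", "x")
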