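"""Cohort statistics for interocular-asymmetry analyses.

The pipeline follows common clinical-study practice: distributional
checks decide between a one-way ANOVA and a Kruskal-Wallis omnibus test;
either path is followed by Dunn's rank-based post hoc with Bonferroni
adjustment over all pairwise contrasts; categorical covariates are tested
by chi-squared with an automatic switch to Fisher's exact test when an
expected cell count falls below 5; continuous associations use Pearson
correlation and covariate-adjusted ordinary least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of a k-group comparison on one outcome."""

    outcome: str
    method: str                      # "anova+dunn-bonferroni" | "kruskal+dunn"
    omnibus_stat: float
    omnibus_p: float
    pairwise: Dict[Tuple[str, str], Dict[str, float]]
    normality_p: float               # min per-group Lilliefors-type KS p
    homogeneity_p: float             # Levene
    group_sizes: Dict[str, int] = field(default_factory=dict)

    def pairwise_p(self, g1: str, g2: str) -> float:
        key = (g1, g2) if (g1, g2) in self.pairwise else (g2, g1)
        return self.pairwise[key]["p_adj"]


@dataclass
class CategoricalAssociation:
    variable: str
    method: str                      # "chi-squared" | "fisher" | "fisher-mc"
    statistic: Optional[float]
    p: float
    min_expected: float
    table: np.ndarray


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int


@dataclass
class RegressionResult:
    outcome: str
    exposure: str
    coefficients: pd.DataFrame       # index: term; beta, ci_low, ci_high, p
    n: int

    @property
    def exposure_beta(self) -> float:
        return float(self.coefficients.loc[self.exposure, "beta"])

    @property
    def exposure_ci(self) -> Tuple[float, float]:
        row = self.coefficients.loc[self.exposure]
        return float(row["ci_low"]), float(row["ci_high"])

    @property
    def exposure_p(self) -> float:
        return float(self.coefficients.loc[self.exposure, "p"])


def _group_values(
    table: pd.DataFrame, outcome: str, group_col: str
) -> Dict[str, np.ndarray]:
    if outcome not in table.columns or group_col not in table.columns:
        raise ValidationError(f"missing column {outcome!r} or {group_col!r}")
    sub = table[[group_col, outcome]].dropna()
    groups = {
        str(g): v[outcome].to_numpy(dtype=float)
        for g, v in sub.groupby(group_col, sort=False, observed=True)
    }
    groups = {g: v for g, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise InsufficientDataError("need at least two non-empty groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {g!r} has n < 2")
    return groups


def _ks_normality_p(values: np.ndarray) -> float:
    """Kolmogorov-Smirnov test against a normal with fitted moments."""
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0
    z = (values - values.mean()) / sd
    return float(sps.kstest(z, "norm").pvalue)


def dunn_posthoc(
    groups: Dict[str, np.ndarray], adjust: str = "bonferroni"
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Dunn's rank-based multiple-comparison z tests with tie correction.

    All observations are ranked jointly; each pairwise z contrast uses

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12 (N - 1)). Two-sided p-values
    are Bonferroni-multiplied by the number of pairs (capped at 1).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, i0 = {}, {}, 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[i0 : i0 + n_g].mean()
        sizes[g] = n_g
        i0 += n_g
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_tot - 1)))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    out = {}
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs) if adjust == "bonferroni" else p_raw
        out[(g1, g2)] = {"z": float(z), "p_raw": float(p_raw),
                         "p_adj": float(p_adj)}
    return out


def compare_groups(
    table: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    method: str = "auto",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Omnibus k-group comparison with Dunn's post hoc.

    With ``method="auto"`` the path is chosen from the data: per-group
    Kolmogorov-Smirnov normality checks and Levene's homogeneity-of-
    variance test; if every group looks normal and variances are
    homogeneous at ``alpha`` the omnibus is a one-way ANOVA
    ("anova+dunn-bonferroni"), otherwise Kruskal-Wallis ("kruskal+dunn").
    Both paths share the rank-based Dunn-Bonferroni pairwise contrasts.
    The chosen path and both check p-values are recorded in the result.
    """
    groups = _group_values(table, outcome, group_col)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise DegenerateDataError(f"outcome {outcome!r} is constant")
    normality_p = min(_ks_normality_p(v) for v in groups.values())
    homogeneity_p = float(sps.levene(*groups.values()).pvalue)
    if method == "auto":
        use_anova = normality_p > alpha and homogeneity_p > alpha
    elif method == "anova":
        use_anova = True
    elif method == "kruskal":
        use_anova = False
    else:
        raise ValidationError(f"unknown method {method!r}")
    if use_anova:
        stat, p = sps.f_oneway(*groups.values())
        chosen = "anova+dunn-bonferroni"
    else:
        stat, p = sps.kruskal(*groups.values())
        chosen = "kruskal+dunn"
    return GroupComparison(
        outcome=outcome,
        method=chosen,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=dunn_posthoc(groups),
        normality_p=float(normality_p),
        homogeneity_p=homogeneity_p,
        group_sizes={g: len(v) for g, v in groups.items()},
    )


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than the observed table's.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 requires a 2x2 table")
    return float(sps.fisher_exact(tab.astype(int)).pvalue)


def _fisher_mc_p(
    table: np.ndarray, n_sim: int = 20000, seed: int = 0
) -> float:
    """Monte-Carlo conditional test for r x c tables with fixed margins,
    ordered by the chi-squared statistic (used when the table is larger
    than 2x2 but expected counts are too small for the asymptotic test)."""
    rng = np.random.default_rng(seed)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    obs_stat = ((table - expected) ** 2 / expected).sum()
    sim = sps.random_table(row, col).rvs(n_sim, random_state=rng)
    sim_stat = ((sim - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((1 + (sim_stat >= obs_stat - 1e-9).sum()) / (1 + n_sim))


def association_test(
    contingency: np.ndarray, variable: str = "", seed: int = 0
) -> CategoricalAssociation:
    """Chi-squared independence test with an automatic exact fallback.

    Pearson chi-squared (no continuity correction) when every expected
    count is at least 5; otherwise Fisher's exact test for 2x2 tables or a
    Monte-Carlo conditional test (flagged ``"fisher-mc"``) for larger
    tables.
    """
    tab = np.asarray(contingency, dtype=float)
    if tab.ndim != 2 or tab.size == 0:
        raise ValidationError("contingency table must be 2-D and non-empty")
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DegenerateDataError(
            f"variable {variable!r}: fewer than two observed levels"
        )
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    min_exp = float(expected.min())
    if min_exp >= 5.0:
        stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
        return CategoricalAssociation(variable, "chi-squared", float(stat),
                                      float(p), min_exp, tab)
    if tab.shape == (2, 2):
        p = fisher_exact_2x2(tab)
        return CategoricalAssociation(variable, "fisher", None, p,
                                      min_exp, tab)
    p = _fisher_mc_p(tab.astype(int), seed=seed)
    return CategoricalAssociation(variable, "fisher-mc", None, p, min_exp, tab)


def categorical_association(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    seed: int = 0,
) -> CategoricalAssociation:
    """Test association between a categorical covariate and group."""
    sub = table[[group_col, variable]].dropna()
    crosstab = pd.crosstab(sub[variable], sub[group_col])
    return association_test(crosstab.to_numpy(), variable=variable, seed=seed)


def correlate(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson correlation on complete cases."""
    sub = table[[x, y]].dropna()
    n = len(sub)
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 complete cases for correlation, got {n}"
        )
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(x=x, y=y, r=float(res.statistic),
                             p=float(res.pvalue), n=n)


_DR_GRADE = {"no DM": 0, "DM without DR": 1, "NPDR": 2, "PDR": 3}

#: default adjustment set for HbA1c-asymmetry regressions
DEFAULT_ADJUSTMENT = (
    "age", "sex", "race", "htn", "hld", "obesity", "group", "insulin",
    "smoking",
)


def _design_matrix(
    table: pd.DataFrame, exposure: str, adjustment: Sequence[str]
) -> Tuple[pd.DataFrame, List[str]]:
    cols: Dict[str, np.ndarray] = {}
    for name in [exposure, *adjustment]:
        if name in cols:
            continue
        if name not in table.columns:
            raise ValidationError(f"missing covariate column {name!r}")
        s = table[name]
        if name == "sex":
            cols["sex"] = (s.astype(str) == "M").astype(float).to_numpy()
        elif name == "race":
            levels = s.value_counts()
            ref = levels.index[0]  # reference = largest level
            for lv in sorted(str(x) for x in levels.index if x != ref):
                cols[f"race[{lv}]"] = (s.astype(str) == lv).astype(float
                                                                   ).to_numpy()
        elif name == "group":
            cols["dr_grade"] = s.map(_DR_GRADE).astype(float).to_numpy()
        else:
            cols[name] = s.astype(float).to_numpy()
    X = pd.DataFrame(cols, index=table.index)
    return X, list(X.columns)


def fit_adjusted_regression(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjustment: Sequence[str] = (),
) -> RegressionResult:
    """Covariate-adjusted ordinary least squares for one AI outcome.

    Categorical covariates are dummy-coded: sex with female as reference,
    race with the largest level as reference, DR group as an ordered grade
    0-3. Inference uses heteroscedasticity-robust (HC3) standard errors,
    since asymmetry indices are strongly heteroscedastic across severity
    groups. Returns per-term beta, 95% CI and p. A rank-deficient design
    raises :class:`CollinearityError` naming the aliased columns.
    """
    needed = {outcome, exposure, *adjustment} & set(table.columns)
    if outcome not in table.columns:
        raise ValidationError(f"missing outcome column {outcome!r}")
    sub = table.dropna(subset=[c for c in needed])
    if len(sub) < 8:
        raise InsufficientDataError(
            f"only {len(sub)} complete cases for regression on {outcome!r}"
        )
    X, names = _design_matrix(sub, exposure, adjustment)
    y = sub[outcome].to_numpy(dtype=float)
    n = len(y)
    if n <= X.shape[1] + 1 + 5:
        raise InsufficientDataError(
            f"n={n} too small for {X.shape[1]} predictors"
        )
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify aliased columns via pivoted QR on the centred design
        aliased = []
        basis: List[np.ndarray] = [np.ones(n) / np.sqrt(n)]
        for cname in X.columns:
            v = X[cname].to_numpy(dtype=float).copy()
            for b in basis:
                v -= (v @ b) * b
            norm = np.linalg.norm(v)
            if norm < 1e-8 * max(1.0, np.linalg.norm(X[cname])):
                aliased.append(cname)
            else:
                basis.append(v / norm)
        raise CollinearityError(aliased or ["<unidentified>"])
    model = sm.OLS(y, Xc).fit(cov_type="HC3")
    ci = model.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "beta": model.params,
            "ci_low": ci[:, 0] if isinstance(ci, np.ndarray) else ci.iloc[:, 0],
            "ci_high": ci[:, 1] if isinstance(ci, np.ndarray) else ci.iloc[:, 1],
            "p": model.pvalues,
        }
    )
    exposure_term = exposure if exposure in coef.index else None
    if exposure_term is None:
        raise ValidationError(f"exposure {exposure!r} absent from design")
    return RegressionResult(outcome=outcome, exposure=exposure,
                            coefficients=coef, n=n)
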