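"""Trait-level statistics: OLS regressions, AICc model ranking, two-way
ANOVA with Tukey HSD, and pairwise correlation matrices.

This is the layer that asks which anatomical or physiological traits
predict the maximum Brix accumulation rate across cultivars, whether
vascular traits differ between climate and berry-color groups, and how
traits co-vary.  Regressions and ANOVA are ordinary least squares
(statsmodels under the hood); AICc uses the Gaussian profile likelihood

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)

with k counting the regression coefficients plus the residual variance,
so only differences between rows of a ranking are meaningful.  Tukey HSD
adjusted p-values come from the studentized-range distribution with the
Tukey–Kramer unequal-n correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "simple_linreg",
    "multiple_linreg",
    "aicc",
    "rank_models",
    "two_way_anova",
    "tukey_hsd",
    "correlation_matrix",
]


class StatsError(ValueError):
    pass


@dataclass
class RegressionResult:
    """OLS fit summary: coefficients (incl. intercept), r², overall-F p."""

    coefficients: pd.Series
    r2: float
    p_value: float
    n: int
    rss: float
    k: int  # number of mean-model parameters (intercept + slopes)


@dataclass
class AnovaResult:
    """Per-term F tests plus optional Tukey pairwise comparisons."""

    table: pd.DataFrame
    residual_df: float
    tukey_pairs: dict = field(default_factory=dict)


def _as_clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def simple_linreg(x, y) -> RegressionResult:
    """Univariate OLS of y on x with intercept.

    Constant y is handled by convention: slope 0, r² = 0.  Constant x is
    a degenerate design and raises.
    """
    x, y = _as_clean_xy(x, y)
    if x.size < 3:
        raise StatsError(f"need >= 3 complete (x, y) pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("degenerate design: x is constant")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else float(fit.rsquared)
    p = 1.0 if tss == 0 else float(fit.f_pvalue)
    return RegressionResult(
        coefficients=pd.Series({"intercept": fit.params[0], "slope": fit.params[1]}),
        r2=r2,
        p_value=p,
        n=int(x.size),
        rss=float(np.sum(fit.resid**2)),
        k=2,
    )


def multiple_linreg(X: pd.DataFrame, y) -> RegressionResult:
    """OLS of y on the columns of X (intercept added).

    Rank-deficient designs raise, naming the columns involved in the
    collinearity.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(y)
    X, y = X.loc[mask], y[mask]
    n, p = X.shape
    if n <= p + 1:
        raise StatsError(f"need n > k: n={n}, predictors={p}")
    design = np.column_stack([np.ones(n), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        culprits = [
            col for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise StatsError(f"rank-deficient design; collinear columns: {culprits}")
    fit = sm.OLS(y, design).fit()
    names = ["intercept", *X.columns]
    return RegressionResult(
        coefficients=pd.Series(fit.params, index=names),
        r2=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        n=int(n),
        rss=float(np.sum(fit.resid**2)),
        k=p + 1,
    )


def aicc(rss: float, n: int, k_params: int) -> float:
    """Small-sample-corrected AIC from a Gaussian least-squares fit.

    ``k_params`` counts the mean-model parameters (intercept + slopes);
    the residual variance adds one, k = k_params + 1.  Undefined when the
    correction denominator n − k − 1 is not positive.
    """
    if rss <= 0:
        raise StatsError("AICc requires rss > 0 (perfect fits have no finite likelihood)")
    k = k_params + 1
    if n - k - 1 <= 0:
        raise StatsError(f"AICc correction undefined: n={n} <= k+1={k + 1}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def rank_models(
    candidates: list[tuple[str, list[str]]],
    data: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit each candidate predictor set and rank by AICc (ascending).

    ``candidates`` is a list of (label, predictor-column list).  All
    models are fitted to the same complete-case rows of ``data`` so their
    AICc values are comparable.  Returns columns model_label, predictors,
    r2, p_value, aicc, significant.
    """
    if not candidates:
        raise StatsError("no candidate models")
    all_cols = sorted({c for _, preds in candidates for c in preds} | {response})
    rows = data[all_cols].dropna()
    y = rows[response]
    out = []
    for label, preds in candidates:
        if not preds:
            raise StatsError(f"model {label!r} has no predictors")
        res = multiple_linreg(rows[preds], y)
        out.append(
            {
                "model_label": label,
                "predictors": "+".join(preds),
                "r2": res.r2,
                "p_value": res.p_value,
                "aicc": aicc(res.rss, res.n, res.k),
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(out).sort_values("aicc", ignore_index=True)


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str | None = None,
    interaction: bool = False,
) -> AnovaResult:
    """ANOVA with Type II sums of squares (one- or two-factor).

    Type II is the conventional choice for main-effect questions on
    mildly unbalanced designs; it coincides with the classical balanced
    decomposition when the design is balanced.  With ``factor_b=None``
    this reduces to a one-way ANOVA.  Interaction terms require every
    factor-level cell to be occupied.
    """
    df = data.dropna(subset=[c for c in (response, factor_a, factor_b) if c]).copy()
    terms = [factor_a] + ([factor_b] if factor_b else [])
    for f in terms:
        if df[f].nunique() < 2:
            raise StatsError(f"factor {f!r} needs >= 2 levels")
    if interaction:
        if factor_b is None:
            raise StatsError("interaction requires two factors")
        cells = df.groupby([factor_a, factor_b], observed=True).size()
        full = df[factor_a].nunique() * df[factor_b].nunique()
        if len(cells) < full:
            raise StatsError("interaction term inestimable: empty factor cells")
    rhs = " + ".join(f"C(Q('{f}'))" for f in terms)
    if interaction:
        rhs += f" + C(Q('{factor_a}')):C(Q('{factor_b}'))"
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=df).fit()
    if model.df_resid < 1:
        raise StatsError("no residual degrees of freedom")
    table = anova_lm(model, typ=2)
    # map patsy term names back to factor names
    rename = {f"C(Q('{f}'))": f for f in terms}
    rename[f"C(Q('{factor_a}')):C(Q('{factor_b}'))"] = f"{factor_a}:{factor_b}"
    table = table.rename(index=rename)
    return AnovaResult(table=table, residual_df=float(model.df_resid))


def _letter_display(groups: list, significant: set[tuple]) -> dict:
    """Compact letter display: groups not sharing a letter differ.

    Insert-and-absorb construction: start with one column holding all
    groups; each significantly different pair splits every column that
    contains both; redundant (subset) columns are absorbed.
    """
    columns: list[set] = [set(groups)]
    for i, j in significant:
        new_cols: list[set] = []
        for col in columns:
            if i in col and j in col:
                new_cols.extend([col - {i}, col - {j}])
            else:
                new_cols.append(col)
        # absorb columns contained in another
        columns = [
            c for idx, c in enumerate(new_cols)
            if c and not any(c < o or (c == o and idx > jdx)
                             for jdx, o in enumerate(new_cols) if jdx != idx)
        ]
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    columns.sort(key=lambda col: min(groups.index(g) for g in col))
    for letter, col in zip(alphabet, columns):
        for g in sorted(col, key=lambda g: groups.index(g)):
            letters[g] += letter
    return letters


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons with a compact letter display.

    Adjusted p-values use the studentized-range distribution with the
    Tukey–Kramer standard error for unequal group sizes.  Returns one row
    per pair (group_1, group_2, diff, se, q, p_adj, reject) with a
    ``letters`` mapping attached in ``DataFrame.attrs``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = np.isfinite(values)
    values, groups = values[mask], groups[mask]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise StatsError("need >= 2 groups")
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise StatsError(f"groups with a single observation: {small}")
    means = {g: float(values[groups == g].mean()) for g in labels}
    n_total = values.size
    k = len(labels)
    df_resid = n_total - k
    mse = sum(np.sum((values[groups == g] - means[g]) ** 2) for g in labels) / df_resid
    rows = []
    sig_pairs = set()
    for g1, g2 in itertools.combinations(labels, 2):
        diff = means[g2] - means[g1]
        se = math.sqrt(mse / 2.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
        else:
            q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        p_adj = min(max(p_adj, 0.0), 1.0)
        reject = p_adj < alpha
        if reject:
            sig_pairs.add((g1, g2))
        rows.append(
            {"group_1": g1, "group_2": g2, "diff": diff, "se": se, "q": q,
             "p_adj": p_adj, "reject": reject}
        )
    out = pd.DataFrame(rows)
    out.attrs["letters"] = _letter_display(labels, sig_pairs)
    return out


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns (r, p) DataFrames.  Cells with fewer than ``min_pairs``
    complete pairs are NaN (flagged, not fatal).
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < min_pairs:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(x[mask], y[mask])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
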