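"""Covariate-adjusted association testing and regression models.

Partial Spearman correlations adjust rank-transformed variables for
covariates by least squares before correlating residuals; multiplicity is
controlled with Benjamini-Hochberg FDR.  Diversity regressions are ordinary
least squares over a formula specification, with helpers for block-wise
variance partitioning and Cohen's d / f effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests


def build_cohort_frame(
    diet_profile: pd.DataFrame,
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Merge diet profile, alpha diversity and metadata on participant ID.

    Only participants present in all three tables are kept; IDs missing from
    any table are reported rather than silently dropped.
    """
    tables = {"diet_profile": diet_profile, "alpha": alpha, "metadata": metadata}
    indexed = {}
    for name, t in tables.items():
        t = t.copy()
        if "participant_id" in t.columns:
            t = t.set_index("participant_id")
        indexed[name] = t
    common = indexed["diet_profile"].index
    for t in indexed.values():
        common = common.intersection(t.index)
    unmatched = {
        name: sorted(set(t.index) - set(common)) for name, t in indexed.items()
    }
    frame = pd.concat([t.loc[common] for t in indexed.values()], axis=1)
    frame.index.name = "participant_id"
    return frame, unmatched


def _rank_residuals(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    ranks = stats.rankdata(values)  # average ranks for ties
    if covariates is None or covariates.shape[1] == 0:
        return ranks - ranks.mean()
    X = np.column_stack([np.ones(len(ranks)), covariates])
    beta, *_ = np.linalg.lstsq(X, ranks, rcond=None)
    return ranks - X @ beta


def partial_spearman(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float, int]:
    """Spearman correlation of x and y after removing covariate effects.

    Rank-transform x and y, regress each on the covariates (with intercept),
    and Pearson-correlate the residuals; p-value is t-based with
    ``df = n - 2 - n_covariates``.  Complete cases only (listwise deletion).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
        C = C[mask]
        k = C.shape[1]
    else:
        mask = ~(np.isnan(x) | np.isnan(y))
        C, k = None, 0
    x, y = x[mask], y[mask]
    n = len(x)
    if n < k + 3:
        raise ValueError(f"partial_spearman: n={n} too small for {k} covariates")
    rx = _rank_residuals(x, C)
    ry = _rank_residuals(y, C)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("partial_spearman: constant variable after ranking/adjustment")
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return rho, p, n


def fdr_adjust(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and discovery flags at ``q``."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def associate(
    frame: pd.DataFrame,
    features: list[str],
    targets: list[str],
    covariates: list[str] | None = None,
    q: float = 0.1,
) -> pd.DataFrame:
    """Partial Spearman of every (feature, target) pair with FDR columns."""
    rows = []
    cov = frame[covariates] if covariates else None
    for f in features:
        for t in targets:
            rho, p, n = partial_spearman(
                frame[f], frame[t], cov if cov is None else cov.to_numpy()
            )
            rows.append({"feature": f, "target": t, "partial_rho": rho,
                         "p_raw": p, "n": n})
    out = pd.DataFrame(rows)
    out["q_fdr"], out["discovery"] = fdr_adjust(out["p_raw"], q=q)
    return out


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, rank = [], 0
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            aliased.append(name)
    return aliased


def fit_diversity_regression(frame: pd.DataFrame, formula: str) -> pd.DataFrame:
    """OLS fit of a diversity outcome on a formula specification.

    Returns a coefficient table (coef, ci_low, ci_high, p_value) indexed by
    term.  Categorical covariates are dummy-coded by the formula; a
    rank-deficient design raises, naming the aliased terms.
    """
    model = smf.ols(formula, data=frame)
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        aliased = _aliased_columns(exog, list(model.exog_names))
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "coef": res.params,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p_value": res.pvalues,
    })
    table.index.name = "term"
    return table


def predict_change(coef_table: pd.DataFrame, deltas: dict[str, float]) -> float:
    """Change in the fitted linear predictor for covariate shifts ``deltas``,
    holding every other term fixed."""
    change = 0.0
    for term, dx in deltas.items():
        if term not in coef_table.index:
            raise KeyError(f"term {term!r} not in coefficient table")
        change += float(coef_table.loc[term, "coef"]) * dx
    return change


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / tss)


def variance_explained(
    frame: pd.DataFrame,
    blocks: dict[str, list[str]],
    outcome: str = "shannon",
) -> dict[str, float]:
    """OLS R-squared of the outcome on each feature block and their union."""
    for name, cols in blocks.items():
        if not cols:
            raise ValueError(f"variance_explained: empty block {name!r}")
    all_cols = sorted({c for cols in blocks.values() for c in cols})
    sub = frame[[outcome] + all_cols].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    out = {
        name: _ols_r2(y, sub[cols].to_numpy(dtype=float))
        for name, cols in blocks.items()
    }
    out["union"] = _ols_r2(y, sub[all_cols].to_numpy(dtype=float))
    return out


@dataclass(frozen=True)
class EffectSize:
    kind: str  # "cohen_d" | "cohen_f"
    value: float


def cohen_d(a, b) -> float:
    """Cohen's d with pooled (n-1) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("cohen_d: each group needs >= 2 observations")
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def cohen_f(groups: list[np.ndarray]) -> float:
    """Cohen's f from one-way ANOVA eta-squared."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("cohen_f: need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = ((allv - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    eta2 = ss_between / ss_total
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def effect_size(values, grouping) -> EffectSize:
    """Cohen's d for binary groupings, Cohen's f for multi-category ones.

    For binary groupings d is computed as (first - second) with group order
    by sorted label.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    grouping = pd.Series(np.asarray(grouping)).astype(str)
    levels = sorted(grouping.unique())
    groups = [values[grouping == lv].to_numpy() for lv in levels]
    if len(levels) < 2:
        raise ValueError("effect_size: need >= 2 groups")
    if len(levels) == 2:
        return EffectSize("cohen_d", cohen_d(groups[0], groups[1]))
    return EffectSize("cohen_f", cohen_f(groups))
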