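"""Bidirectional prediction harness.

Classifies extreme quartiles (Q1 vs Q4) of a continuous target, or regresses
over its full range, using gradient-boosted trees over repeated 80:20
train-test splits; per-feature gain importances are aggregated across
iterations.  The boosted-tree learner is consumed from scikit-learn
(``GradientBoostingClassifier`` / ``GradientBoostingRegressor``); the
harness itself - labeling, transformation, splitting, evaluation,
aggregation - is the computation of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split


@dataclass(frozen=True)
class HarnessConfig:
    """Hyperparameters and evaluation protocol for one harness run.

    Classifier defaults follow a microbiome-tuned boosted-tree setup
    (1000 trees, depth 6, 0.8 column / 0.4 row subsampling, learning rate
    0.005); the regressor uses 1000 trees at learning rate 0.05.
    ``l1_alpha`` is retained for config compatibility but unused: the
    scikit-learn learner exposes no L1 leaf penalty.
    """

    task: str = "classify"  # classify | regress
    n_iterations: int = 100
    test_fraction: float = 0.2
    trees: int = 1000
    max_depth: int = 6
    column_subsample: float = 0.8
    row_subsample: float = 0.4
    l1_alpha: float = 0.1
    learning_rate: float = 0.005
    regress_trees: int = 1000
    regress_learning_rate: float = 0.05
    log_transform_threshold: float = 0.001
    log_transform_offset: float = 1e-6
    seed_base: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")


@dataclass
class HarnessResult:
    iterations: pd.DataFrame       # per-iteration metrics
    importances: pd.Series         # mean gain importance per feature
    label_report: dict             # quartile cuts and class sizes (classification)


def make_extreme_quartile_labels(values: pd.Series) -> tuple[pd.Series, dict]:
    """Binary Q1/Q4 labels from 25th/75th percentile cuts.

    Values at or below the 25th percentile are class 0 (Q1), at or above the
    75th are class 1 (Q4); the middle half is NaN.  Quantiles use linear
    interpolation.
    """
    v = values.dropna()
    if len(v) < 8:
        raise ValueError("make_extreme_quartile_labels: need >= 8 non-missing values")
    q25, q75 = np.quantile(v.to_numpy(dtype=float), [0.25, 0.75])
    if q25 == q75:
        raise ValueError("degenerate distribution: quartile cuts coincide")
    labels = pd.Series(np.nan, index=values.index, dtype=float)
    labels[values <= q25] = 0.0
    labels[values >= q75] = 1.0
    report = {
        "q25": float(q25),
        "q75": float(q75),
        "n_q1": int((labels == 0).sum()),
        "n_q4": int((labels == 1).sum()),
    }
    return labels, report


def apply_log_transform(
    features: pd.DataFrame, threshold: float = 0.001, offset: float = 1e-6
) -> pd.DataFrame:
    """log10(x + offset) for columns whose mean is below ``threshold``.

    Applies only to nonnegative columns (abundance-scale features); columns
    taking negative values are left untouched.
    """
    out = features.copy()
    for col in out.columns:
        if out[col].min() >= 0 and out[col].mean() < threshold:
            out[col] = np.log10(out[col] + offset)
    return out


def _make_learner(config: HarnessConfig, seed: int):
    if config.task == "classify":
        return GradientBoostingClassifier(
            n_estimators=config.trees,
            max_depth=config.max_depth,
            max_features=config.column_subsample,
            subsample=config.row_subsample,
            learning_rate=config.learning_rate,
            random_state=seed,
        )
    return GradientBoostingRegressor(
        n_estimators=config.regress_trees,
        learning_rate=config.regress_learning_rate,
        random_state=seed,
    )


def run_harness(
    features: pd.DataFrame, target: pd.Series, config: HarnessConfig
) -> HarnessResult:
    """Repeated-split evaluation of target predictability from features.

    Classification builds extreme-quartile labels internally and uses
    stratified splits; regression uses the full target range with plain
    random splits.  Iteration i uses seed ``seed_base + i``.
    """
    target = target.reindex(features.index)
    X_all = apply_log_transform(
        features, config.log_transform_threshold, config.log_transform_offset
    )
    label_report: dict = {}
    if config.task == "classify":
        labels, label_report = make_extreme_quartile_labels(target)
        mask = labels.notna() & X_all.notna().all(axis=1)
        X, y = X_all[mask], labels[mask]
    else:
        mask = target.notna() & X_all.notna().all(axis=1)
        X, y = X_all[mask], target[mask]

    rows, importances = [], []
    for i in range(config.n_iterations):
        seed = config.seed_base + i
        strat = y if config.task == "classify" else None
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=config.test_fraction, random_state=seed, stratify=strat
        )
        if config.task == "classify" and y_te.value_counts().min() < 5:
            warnings.warn(f"iteration {i}: test class with <5 members, skipped",
                          stacklevel=2)
            continue
        learner = _make_learner(config, seed)
        learner.fit(X_tr.to_numpy(), y_tr.to_numpy())
        if config.task == "classify":
            scores = learner.predict_proba(X_te.to_numpy())[:, 1]
            rows.append({
                "iteration": i, "seed": seed,
                "auroc": roc_auc_score(y_te, scores),
                "auprc": average_precision_score(y_te, scores),
            })
        else:
            pred = learner.predict(X_te.to_numpy())
            rho = stats.spearmanr(y_te, pred).statistic
            rows.append({"iteration": i, "seed": seed, "spearman_rho": rho})
        importances.append(learner.feature_importances_)

    iterations = pd.DataFrame(rows)
    mean_imp = (
        pd.Series(np.mean(importances, axis=0), index=X.columns, name="mean_gain")
        if importances else pd.Series(dtype=float, name="mean_gain")
    )
    return HarnessResult(iterations, mean_imp, label_report)


ALPHA_METRICS = ["faith_pd", "shannon", "observed_features", "pielou"]


def predict_alpha_from_diet(
    frame: pd.DataFrame,
    config: HarnessConfig,
    alpha_metrics: list[str] | None = None,
    feature_cols: list[str] | None = None,
) -> dict[str, HarnessResult]:
    """One harness run per alpha-diversity metric, predicted from diet,
    regularity and anthropometric columns of the cohort frame."""
    metrics = alpha_metrics if alpha_metrics is not None else ALPHA_METRICS
    metrics = [m for m in metrics if m in frame.columns]
    if feature_cols is None:
        exclude = set(ALPHA_METRICS)
        feature_cols = [
            c for c in frame.columns
            if c not in exclude and pd.api.types.is_numeric_dtype(frame[c])
        ]
    results = {}
    for m in metrics:
        features = frame[feature_cols].dropna(axis=1, how="all")
        features = features.loc[:, features.nunique() > 1]
        results[m] = run_harness(features, frame[m], config)
    return results
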