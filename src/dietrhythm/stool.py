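"""Stool-quality features from daily self-reports.

Daily reports use the closed vocabulary {great, normal, constipated,
diarrhea}.  Participants reporting at least ``min_days`` days receive
per-category proportions; top-k classification assigns one label per
participant with precedence diarrhea > constipated > great > normal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .assoc import partial_spearman

CATEGORIES = ["great", "normal", "constipated", "diarrhea"]


def validate_reports(reports: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "date", "category"}
    missing = required - set(reports.columns)
    if missing:
        raise ValueError(f"stool reports missing columns: {sorted(missing)}")
    bad = sorted(set(reports["category"]) - set(CATEGORIES))
    if bad:
        raise ValueError(f"unknown stool categories: {bad}")
    dup = reports.duplicated(subset=["participant_id", "date"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate participant-day stool reports"
        )
    return reports


def stool_proportions(reports: pd.DataFrame, min_days: int = 5) -> pd.DataFrame:
    """Per-participant category proportions over reported days.

    Participants with fewer than ``min_days`` reports are excluded.  The
    denominator is the number of *reported* days.
    """
    reports = validate_reports(reports)
    counts = (
        reports.groupby(["participant_id", "category"]).size().unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
    )
    n_days = counts.sum(axis=1)
    keep = n_days >= min_days
    counts, n_days = counts.loc[keep], n_days[keep]
    profile = counts.div(n_days, axis=0)
    profile.columns = [f"{c}_proportion" for c in profile.columns]
    profile.insert(0, "n_reported_days", n_days)
    return profile


def classify_stool_users(
    profiles: pd.DataFrame, k_great: int = 50, k_extreme: int = 20
) -> pd.DataFrame:
    """Assign one stool-quality label per participant by top-k proportions.

    Top ``k_extreme`` by diarrhea proportion are labeled diarrhea, then the
    top ``k_extreme`` remaining by constipated proportion, then the top
    ``k_great`` remaining by great proportion; everyone else is normal.
    Extreme/great labels require a strictly positive proportion; ties at the
    k-th rank break by participant ID.
    """
    if len(profiles) < k_great + 2 * k_extreme:
        warnings.warn(
            f"only {len(profiles)} profiles for top-{k_great}/{k_extreme} "
            "classification; labels will be sparse", stacklevel=2,
        )
    out = profiles.copy()
    out["stool_class"] = "normal"
    remaining = out.index

    for label, col, k in [
        ("diarrhea", "diarrhea_proportion", k_extreme),
        ("constipated", "constipated_proportion", k_extreme),
        ("great", "great_proportion", k_great),
    ]:
        cand = out.loc[remaining]
        cand = cand[cand[col] > 0]
        order = cand.sort_index().sort_values(col, ascending=False, kind="mergesort")
        chosen = order.index[:k]
        out.loc[chosen, "stool_class"] = label
        remaining = remaining.difference(chosen)
    return out


def stool_associations(
    profiles: pd.DataFrame,
    frame: pd.DataFrame,
    min_abs_r: float = 0.15,
    outcomes: tuple[str, ...] = ("great_proportion", "diarrhea_proportion"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations of stool outcomes against cohort-frame columns.

    Returns (full table, filtered table at |r| >= min_abs_r).
    """
    merged = profiles.join(frame, how="inner")
    if len(merged) < 10:
        warnings.warn(f"stool_associations: only n={len(merged)} merged participants",
                      stacklevel=2)
    feature_cols = [
        c for c in frame.columns
        if c not in profiles.columns and pd.api.types.is_numeric_dtype(frame[c])
    ]
    rows = []
    for outcome in outcomes:
        if merged[outcome].nunique() < 2:
            continue
        for col in feature_cols:
            sub = merged[[outcome, col]].dropna()
            if len(sub) < 3 or sub[col].nunique() < 2 or sub[outcome].nunique() < 2:
                continue
            rho, p, n = partial_spearman(sub[outcome], sub[col], covariates=None)
            rows.append({"outcome": outcome, "feature": col,
                         "spearman_r": rho, "p_raw": p, "n": n})
    full = pd.DataFrame(rows)
    filtered = full[full["spearman_r"].abs() >= min_abs_r].reset_index(drop=True)
    return full, filtered
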