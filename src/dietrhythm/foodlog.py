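"""Food-log parsing, validation, per-day aggregation and QC filtering.

A food log is a long-format table of eating events: one row per
(participant, date, item) with a food-group label, grams, kcal and nutrient
columns.  ``aggregate_daily`` collapses it to one row per participant-day;
``qc_filter`` applies the energy and minimum-tracking-day exclusions used
before any regularity metric is computed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Nutrient columns carried by a food log (grams unless noted).
NUTRIENT_COLUMNS = [
    "fiber",          # g
    "protein",        # g
    "fat",            # g
    "carbohydrate",   # g
    "sfa",            # g
    "mufa",           # g
    "pufa",           # g
    "sodium",         # g
    "added_sugar",    # g
    "potassium",      # mg
    "magnesium",      # mg
    "folate",         # ug
    "iron",           # mg
    "calcium",        # mg
    "phosphorus",     # mg
    "zinc",           # mg
    "vitamin_c",      # mg
    "niacin",         # mg
    "alcohol",        # g
]

REQUIRED_COLUMNS = ["participant_id", "date", "item_id", "food_group", "grams", "kcal"]

KCAL_PREFIX = "kcal__"


def read_food_log(path: str | Path, vocabulary: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV/CSV food log and validate it.

    The separator is inferred from the extension (``.csv`` -> comma,
    otherwise tab).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    log = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "item_id": str})
    return validate_food_log(log, vocabulary=vocabulary)


def validate_food_log(log: pd.DataFrame, vocabulary: list[str] | None = None) -> pd.DataFrame:
    """Validate a food-log frame: required columns, non-negative amounts,
    parseable dates normalised to ISO-8601, declared food groups."""
    missing = [c for c in REQUIRED_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"food log missing required columns: {missing}")
    log = log.copy()
    if (log["grams"] < 0).any() or (log["kcal"] < 0).any():
        raise ValueError("grams and kcal must be non-negative")
    log["date"] = pd.to_datetime(log["date"]).dt.strftime("%Y-%m-%d")
    if vocabulary is not None:
        unknown = sorted(set(log["food_group"]) - set(vocabulary))
        if unknown:
            raise ValueError(f"unknown food groups: {unknown}")
    return log


def aggregate_daily(log: pd.DataFrame, vocabulary: list[str] | None = None) -> pd.DataFrame:
    """Aggregate a food log to one row per participant-day.

    Output columns: per-food-group grams, per-group kcal (``kcal__<group>``),
    nutrient totals, ``energy_kcal`` and total ``grams``.  Missing nutrient
    cells are treated as 0 (the number imputed is logged).  Row order of the
    input is irrelevant.
    """
    log = validate_food_log(log, vocabulary=vocabulary)
    groups = vocabulary if vocabulary is not None else sorted(log["food_group"].unique())

    out_cols = (
        [f"{g}" for g in groups]
        + [f"{KCAL_PREFIX}{g}" for g in groups]
        + NUTRIENT_COLUMNS
        + ["energy_kcal", "grams_total"]
    )
    if log.empty:
        empty = pd.DataFrame(columns=["participant_id", "date"] + out_cols)
        return empty

    nut_present = [c for c in NUTRIENT_COLUMNS for _ in [0] if c in log.columns]
    n_missing_cells = int(log[nut_present].isna().sum().sum()) if nut_present else 0
    absent_cols = [c for c in NUTRIENT_COLUMNS if c not in log.columns]
    if n_missing_cells or absent_cols:
        logger.info(
            "aggregate_daily: imputed %d missing nutrient cells; absent columns "
            "treated as zero: %s", n_missing_cells, absent_cols,
        )
    work = log.copy()
    for c in NUTRIENT_COLUMNS:
        work[c] = pd.to_numeric(work[c], errors="coerce").fillna(0.0) if c in work.columns else 0.0

    key = ["participant_id", "date"]
    grams_wide = (
        work.pivot_table(index=key, columns="food_group", values="grams",
                         aggfunc="sum", fill_value=0.0)
        .reindex(columns=groups, fill_value=0.0)
    )
    kcal_wide = (
        work.pivot_table(index=key, columns="food_group", values="kcal",
                         aggfunc="sum", fill_value=0.0)
        .reindex(columns=groups, fill_value=0.0)
    )
    kcal_wide.columns = [f"{KCAL_PREFIX}{g}" for g in kcal_wide.columns]
    totals = work.groupby(key)[NUTRIENT_COLUMNS + ["kcal", "grams"]].sum()
    totals = totals.rename(columns={"kcal": "energy_kcal", "grams": "grams_total"})

    daily = pd.concat([grams_wide, kcal_wide, totals], axis=1).reset_index()
    daily = daily.sort_values(key, kind="mergesort").reset_index(drop=True)
    return daily


def qc_filter(
    daily: pd.DataFrame,
    min_kcal: float = 1000.0,
    min_days: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-energy days and under-tracked participants.

    Days with ``energy_kcal < min_kcal`` are removed; participants left with
    fewer than ``min_days`` days are removed entirely.  Returns the filtered
    table and a per-participant exclusion report with columns
    ``days_input``, ``days_low_energy``, ``days_kept``, ``excluded``,
    ``reason``.  Idempotent.
    """
    if daily.empty:
        report = pd.DataFrame(
            columns=["participant_id", "days_input", "days_low_energy",
                     "days_kept", "excluded", "reason"]
        )
        return daily.copy(), report

    low = daily["energy_kcal"] < min_kcal
    kept_days = daily.loc[~low]
    per_part = pd.DataFrame({
        "days_input": daily.groupby("participant_id").size(),
        "days_low_energy": low.groupby(daily["participant_id"]).sum().astype(int),
    })
    per_part["days_kept"] = per_part["days_input"] - per_part["days_low_energy"]
    per_part["excluded"] = per_part["days_kept"] < min_days
    per_part["reason"] = np.where(
        per_part["excluded"], f"fewer than {min_days} days with >= {min_kcal:g} kcal", ""
    )
    report = per_part.reset_index().rename(columns={"index": "participant_id"})

    keep_ids = per_part.index[~per_part["excluded"]]
    filtered = kept_days[kept_days["participant_id"].isin(keep_ids)].reset_index(drop=True)
    if filtered.empty:
        logger.warning("qc_filter: no participant-days survived filtering")
    return filtered, report
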