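"""Differential-effect estimation and reference-frame log ratios.

Per-taxon effects of a dietary variable are estimated as OLS slopes of CLR
abundance on the standardized variable, with bootstrap percentile intervals
standing in for Bayesian highest-density intervals (a taxon is "credible"
when its interval excludes zero).  Credible taxa are split by effect sign
into numerator/denominator reference frames whose summed counts define a
per-sample base-10 log ratio; externally computed effect tables (e.g. from
a negative-binomial Bayesian model) can be ingested via ``read_effects``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .micro import FeatureTable, _as_frame, clr_transform

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = ["mean_effect", "interval_low", "interval_high", "credible"]


def estimate_effects(
    table,
    variable: pd.Series,
    n_boot: int = 500,
    seed: int | None = None,
    pseudocount: float = 1.0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-taxon slope of CLR abundance on the standardized variable.

    ``mean_effect`` is the full-data slope per 1 SD of the variable;
    intervals are sample-level bootstrap percentiles over ``n_boot``
    resamples (re-standardizing within each resample).  Returns a frame
    indexed by taxon with columns mean_effect, interval_low, interval_high,
    credible.
    """
    df = _as_frame(table)
    v = variable.reindex(df.index)
    mask = v.notna()
    df, v = df.loc[mask], v.loc[mask].to_numpy(dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("estimate_effects: fewer than 3 usable samples")
    if np.std(v) == 0:
        raise ValueError("estimate_effects: variable is constant")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: intervals will be unstable", stacklevel=2)

    clr = clr_transform(df, pseudocount=pseudocount).to_numpy()

    def _slopes(c: np.ndarray, x: np.ndarray) -> np.ndarray:
        sd = x.std()
        if sd == 0:
            return np.full(c.shape[1], np.nan)
        z = (x - x.mean()) / sd
        return z @ c / len(z)  # z has mean 0, var 1 -> cov(C, z)

    point = _slopes(clr, v)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, clr.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _slopes(clr[idx], v[idx])
    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    low = np.nanpercentile(boots, lo_q, axis=0)
    high = np.nanpercentile(boots, hi_q, axis=0)
    # percentile intervals almost always bracket the point estimate; enforce
    # the type invariant in the rare skewed case
    low = np.minimum(low, point)
    high = np.maximum(high, point)
    credible = (low > 0) | (high < 0)
    return pd.DataFrame(
        {"mean_effect": point, "interval_low": low, "interval_high": high,
         "credible": credible},
        index=pd.Index(df.columns, name="taxon_id"),
    )


def read_effects(path: str | Path) -> pd.DataFrame:
    """Ingest an externally computed effect table (TSV with taxon_id index).

    Must provide mean_effect, interval_low, interval_high; ``credible`` is
    derived from the interval when absent.
    """
    eff = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in EFFECT_COLUMNS[:3] if c not in eff.columns]
    if missing:
        raise ValueError(f"effect table missing columns: {missing}")
    if "credible" not in eff.columns:
        eff["credible"] = (eff["interval_low"] > 0) | (eff["interval_high"] < 0)
    bad = ~((eff["interval_low"] <= eff["mean_effect"]) & (eff["mean_effect"] <= eff["interval_high"]))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows violate interval_low <= mean_effect <= interval_high")
    return eff[EFFECT_COLUMNS]


def select_reference_frames(
    effects: pd.DataFrame,
    top_k: int = 100,
    variable_name: str = "variable",
) -> tuple[list[str], list[str]]:
    """Split the top-k credible taxa (by |mean_effect|) by effect sign.

    Ties at the k-th rank are broken by taxon ID so selection is
    deterministic.  Raises when fewer than 2 credible taxa exist or either
    side would be empty.
    """
    cred = effects[effects["credible"]].copy()
    if len(cred) < 2:
        raise ValueError(
            f"select_reference_frames({variable_name}): fewer than 2 credible taxa"
        )
    strength = cred["mean_effect"].abs().to_numpy()
    order = np.lexsort((cred.index.to_numpy(), -strength))
    top = cred.iloc[order].head(top_k)
    numerator = sorted(top.index[top["mean_effect"] > 0])
    denominator = sorted(top.index[top["mean_effect"] < 0])
    if not numerator or not denominator:
        side = "numerator" if not numerator else "denominator"
        raise ValueError(
            f"select_reference_frames({variable_name}): empty {side} group"
        )
    return numerator, denominator


def compute_log_ratio(
    table,
    numerator: list[str],
    denominator: list[str],
    metadata: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample log10 of summed numerator counts over summed denominator.

    Samples with a zero sum on either side, or null metadata, are dropped and
    reported.  Returns (series, dropped) frames.
    """
    num_set, den_set = set(numerator), set(denominator)
    if not num_set or not den_set:
        raise ValueError("numerator and denominator must be non-empty")
    if num_set & den_set:
        raise ValueError(f"overlapping taxa: {sorted(num_set & den_set)}")
    df = _as_frame(table)
    s_num = df[list(numerator)].sum(axis=1)
    s_den = df[list(denominator)].sum(axis=1)

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[s_num == 0] = "zero numerator"
    reasons[s_den == 0] = "zero denominator"
    reasons[(s_num == 0) & (s_den == 0)] = "zero numerator and denominator"
    if metadata is not None:
        null_meta = metadata.reindex(df.index).isna()
        reasons[null_meta & (reasons == "")] = "null metadata"
    drop = reasons != ""

    series = pd.DataFrame(
        {"log_ratio": np.log10(s_num[~drop] / s_den[~drop])},
        index=df.index[~drop],
    )
    series.index.name = "sample_id"
    dropped = pd.DataFrame({"reason": reasons[drop]})
    dropped.index.name = "sample_id"
    return series, dropped


def correlate_log_ratio(
    series: pd.DataFrame, variable: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of the retained log ratios with a variable."""
    merged = series.join(variable.rename("variable"), how="inner").dropna()
    n = len(merged)
    if n < 3:
        raise ValueError("correlate_log_ratio: fewer than 3 retained samples")
    r, p = stats.pearsonr(merged["log_ratio"], merged["variable"])
    return float(r), float(p), n
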