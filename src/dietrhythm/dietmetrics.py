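"""Per-participant diet metrics.

Implements a standard-agnostic density scoring engine for diet-quality
indices (the shipped config transcribes HEI-2020), a day-wise variant of the
total score, coefficient-of-variation regularity metrics, and kilocalorie
based dietary diversity indices (DDS, Shannon, Gini-Simpson).

Two total-score paths exist on purpose:

* ``hei_standard`` scores the across-day *mean* intake once (the
  conventional index), while
* ``hei_daily`` scores each tracking day separately and averages the day
  scores, capturing day-to-day quality regularity.

They coincide exactly when a participant eats the same menu every day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .foodlog import KCAL_PREFIX, NUTRIENT_COLUMNS

ADEQUACY = "adequacy"
MODERATION = "moderation"


@dataclass(frozen=True)
class ComponentSpec:
    """One scored component of a density-based diet index.

    ``full_score_at`` / ``zero_score_at`` are density cut-points; scores are
    linearly interpolated between them and clamped to [0, max_points].
    """

    name: str
    direction: str
    max_points: float
    basis: str  # per_1000kcal | percent_energy | ratio
    numerator: tuple[str, ...]
    full_score_at: float
    zero_score_at: float
    denominator: tuple[str, ...] = ()
    grams_per_unit: float = 1.0
    energy_per_gram: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (ADEQUACY, MODERATION):
            raise ValueError(f"{self.name}: direction must be adequacy or moderation")
        if self.basis not in ("per_1000kcal", "percent_energy", "ratio"):
            raise ValueError(f"{self.name}: unknown basis {self.basis!r}")
        if self.direction == ADEQUACY and not self.full_score_at > self.zero_score_at:
            raise ValueError(f"{self.name}: adequacy requires full_score_at > zero_score_at")
        if self.direction == MODERATION and not self.full_score_at < self.zero_score_at:
            raise ValueError(f"{self.name}: moderation requires full_score_at < zero_score_at")
        if self.basis == "percent_energy" and self.energy_per_gram is None:
            raise ValueError(f"{self.name}: percent_energy basis needs energy_per_gram")
        if self.basis == "ratio" and not self.denominator:
            raise ValueError(f"{self.name}: ratio basis needs a denominator")
        if self.grams_per_unit <= 0:
            raise ValueError(f"{self.name}: grams_per_unit must be positive")


def load_component_specs(path: str | Path | None = None) -> list[ComponentSpec]:
    """Load component specs from YAML; defaults to the shipped HEI-2020 set."""
    if path is None:
        with resources.files("dietrhythm.data").joinpath("hei2020.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    specs = []
    for entry in raw["components"]:
        entry = dict(entry)
        entry["numerator"] = tuple(entry["numerator"])
        if "denominator" in entry:
            entry["denominator"] = tuple(entry["denominator"])
        specs.append(ComponentSpec(**entry))
    return specs


def _col_sum(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    total = pd.Series(0.0, index=df.index)
    for c in cols:
        if c in df.columns:
            total = total + df[c]
    return total


def component_density(intake: pd.DataFrame, spec: ComponentSpec) -> pd.Series:
    """Energy-adjusted density of one component for each row of ``intake``.

    ``intake`` must carry an ``energy_kcal`` column plus whatever numerator
    (and denominator) columns the spec references; absent columns count 0.
    """
    num = _col_sum(intake, spec.numerator)
    if spec.basis == "ratio":
        den = _col_sum(intake, spec.denominator)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = num.to_numpy() / den.to_numpy()
        d = np.where(den.to_numpy() == 0, np.where(num.to_numpy() > 0, np.inf, 0.0), d)
        return pd.Series(d, index=intake.index)
    energy = intake["energy_kcal"]
    if (energy <= 0).any():
        raise ValueError("component_density: zero or negative total energy")
    if spec.basis == "per_1000kcal":
        return (num / spec.grams_per_unit) / energy * 1000.0
    # percent_energy
    return num * spec.energy_per_gram / energy * 100.0


def score_component(density, spec: ComponentSpec):
    """Score a density against a component spec (vectorised; clamped)."""
    d = np.asarray(density, dtype=float)
    if spec.direction == ADEQUACY:
        frac = (d - spec.zero_score_at) / (spec.full_score_at - spec.zero_score_at)
    else:
        frac = (spec.zero_score_at - d) / (spec.zero_score_at - spec.full_score_at)
    score = spec.max_points * np.clip(frac, 0.0, 1.0)
    return float(score) if np.isscalar(density) else score


def total_score(intake: pd.DataFrame, specs: list[ComponentSpec]) -> pd.Series:
    """Sum of component scores per row of a per-day (or mean) intake table."""
    total = np.zeros(len(intake))
    for spec in specs:
        total = total + score_component(component_density(intake, spec), spec)
    return pd.Series(total, index=intake.index)


def _numeric_cols(daily: pd.DataFrame) -> list[str]:
    return [c for c in daily.columns if c not in ("participant_id", "date")]


def hei_standard(daily: pd.DataFrame, specs: list[ComponentSpec]) -> pd.Series:
    """Single score per participant from across-day mean intakes."""
    means = daily.groupby("participant_id")[_numeric_cols(daily)].mean()
    return total_score(means, specs).rename("hei")


def hei_daily(daily: pd.DataFrame, specs: list[ComponentSpec]) -> tuple[pd.Series, pd.DataFrame]:
    """Mean of per-day scores per participant, plus the per-day series."""
    day_scores = daily[["participant_id", "date"]].copy()
    day_scores["hei"] = total_score(daily, specs).to_numpy()
    per_participant = day_scores.groupby("participant_id")["hei"].mean().rename("hei_daily")
    return per_participant, day_scores


def compute_cv(series) -> float:
    """Coefficient of variation in percent: sample SD / mean x 100.

    Returns NaN when the series has fewer than two values or zero mean.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.std(ddof=1) / m * 100.0)


def cv_table(daily: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Per-participant CV (%) for each requested per-day variable.

    Defaults to every numeric column except per-group kcal mirrors.
    """
    if variables is None:
        variables = [c for c in _numeric_cols(daily) if not c.startswith(KCAL_PREFIX)]
    grouped = daily.groupby("participant_id")
    out = {}
    for v in variables:
        out[f"cv_{v}"] = grouped[v].apply(compute_cv)
    return pd.DataFrame(out)


def diet_diversity_daily(
    daily: pd.DataFrame,
    groups: list[str],
    dds_threshold: float = 0.0,
) -> pd.DataFrame:
    """Across-day means of day-wise dietary diversity metrics.

    Per day: shares ``p_g`` are each group's kilocalorie fraction;
    DDS counts groups with grams strictly above ``dds_threshold``;
    Shannon is -sum p ln p (nats); Gini-Simpson is 1 - sum p^2.
    """
    kcal_cols = [f"{KCAL_PREFIX}{g}" for g in groups]
    missing = [c for c in kcal_cols if c not in daily.columns]
    if missing:
        raise ValueError(f"diet_diversity_daily: missing kcal columns {missing}")
    kcal = daily[kcal_cols].to_numpy(dtype=float)
    totals = kcal.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("diet_diversity_daily: day with zero kilocalories")
    p = kcal / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    gini = 1.0 - (p**2).sum(axis=1)
    grams = daily[groups].to_numpy(dtype=float)
    dds = (grams > dds_threshold).sum(axis=1)

    per_day = pd.DataFrame({
        "participant_id": daily["participant_id"].to_numpy(),
        "dds": dds,
        "diet_shannon": shannon,
        "gini_simpson": gini,
    })
    out = per_day.groupby("participant_id").mean()
    out.columns = ["dds_mean", "diet_shannon_mean", "gini_simpson_mean"]
    return out


def build_diet_profile(
    daily: pd.DataFrame,
    specs: list[ComponentSpec] | None = None,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-participant diet profile.

    Columns: ``hei``, ``hei_daily``, diversity indices, ``cv_<var>`` for each
    per-day variable, ``mean_<var>`` mean intakes and ``energy_kcal_mean``.
    """
    if specs is None:
        specs = load_component_specs()
    if groups is None:
        groups = [c[len(KCAL_PREFIX):] for c in daily.columns if c.startswith(KCAL_PREFIX)]
    hei = hei_standard(daily, specs)
    heid, _ = hei_daily(daily, specs)
    divers = diet_diversity_daily(daily, groups)
    cvs = cv_table(daily)
    mean_vars = [c for c in _numeric_cols(daily) if not c.startswith(KCAL_PREFIX)]
    means = daily.groupby("participant_id")[mean_vars].mean()
    means.columns = [f"mean_{c}" for c in means.columns]
    profile = pd.concat([hei, heid, divers, cvs, means], axis=1)
    profile.index.name = "participant_id"
    return profile
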