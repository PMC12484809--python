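"""Seeded synthetic cohorts with planted diet-microbiome effects.

``generate_cohort`` emits a complete cohort (food log, taxa counts, rooted
tree, participant metadata, stool reports, and a truth table of the planted
latents) whose statistical structure is controlled:

* daily food-group intakes are gamma-distributed with a per-participant
  target coefficient of variation (shape = 1/CV^2, scale = mean * CV^2),
* a latent microbial-diversity target is linear in the participant's
  day-wise diet-quality score (slope ``effect_hei_diversity``) and target
  CV (slope ``effect_cv_diversity``, expected negative), plus noise,
* taxa counts are Dirichlet-multinomial along a one-parameter family in
  which a designated responder-taxon block's concentration rises with the
  diversity target - so realized Shannon diversity correlates positively
  with diet quality and negatively with intake irregularity, with the
  planted linear slope preserved in expectation,
* stool categories are drawn daily from a categorical distribution whose
  great/diarrhea probabilities shift with the diet-quality z-score.

All randomness flows from one root seed through named substreams
(foodlog / counts / tree / stool / meta / latent), so adding a component
never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import substream, substream_seed
from .dietmetrics import hei_daily, load_component_specs
from .foodlog import NUTRIENT_COLUMNS, aggregate_daily, qc_filter
from .micro import FeatureTable, write_newick


@dataclass(frozen=True)
class FoodGroupSpec:
    """Mean-intake distribution and nutrient densities for one food group.

    ``mean_g`` is the cohort-median daily intake (log-normal across
    participants with log-scale ``sigma_log``); ``eat_prob`` is the daily
    probability the group is eaten at all; ``nutrients`` are per-gram
    densities in the food-log units.
    """

    name: str
    mean_g: float
    kcal_per_g: float
    eat_prob: float = 1.0
    sigma_log: float = 0.4
    nutrients: dict = field(default_factory=dict)


DEFAULT_FOOD_GROUPS: list[FoodGroupSpec] = [
    FoodGroupSpec("vegetables", 220, 0.30, 1.0, 0.4,
                  {"fiber": 0.025, "carbohydrate": 0.05, "potassium": 2.5,
                   "magnesium": 0.15, "folate": 0.4, "iron": 0.008, "vitamin_c": 0.3}),
    FoodGroupSpec("greens_beans", 60, 0.50, 0.6, 0.5,
                  {"fiber": 0.035, "protein": 0.04, "carbohydrate": 0.08,
                   "potassium": 3.0, "magnesium": 0.3, "folate": 1.0,
                   "iron": 0.02, "vitamin_c": 0.2}),
    FoodGroupSpec("fruits", 180, 0.55, 0.9, 0.4,
                  {"fiber": 0.022, "carbohydrate": 0.12, "potassium": 1.8,
                   "magnesium": 0.1, "folate": 0.2, "vitamin_c": 0.35}),
    FoodGroupSpec("whole_grains", 90, 2.5, 0.8, 0.5,
                  {"fiber": 0.08, "protein": 0.10, "carbohydrate": 0.60,
                   "magnesium": 1.0, "iron": 0.03, "zinc": 0.02,
                   "niacin": 0.04, "phosphorus": 2.5}),
    FoodGroupSpec("refined_grains", 140, 2.6, 1.0, 0.35,
                  {"fiber": 0.02, "protein": 0.08, "carbohydrate": 0.70,
                   "sodium": 0.004, "iron": 0.01, "niacin": 0.03, "phosphorus": 1.0}),
    FoodGroupSpec("dairy", 200, 0.8, 0.9, 0.4,
                  {"protein": 0.034, "fat": 0.03, "sfa": 0.019,
                   "carbohydrate": 0.05, "calcium": 1.2, "phosphorus": 0.9,
                   "potassium": 1.5, "zinc": 0.004}),
    FoodGroupSpec("meat", 110, 2.0, 0.9, 0.45,
                  {"protein": 0.26, "fat": 0.12, "sfa": 0.045, "mufa": 0.05,
                   "pufa": 0.015, "iron": 0.02, "zinc": 0.04, "niacin": 0.08,
                   "phosphorus": 2.0, "sodium": 0.001}),
    FoodGroupSpec("seafood_plant_proteins", 50, 1.5, 0.6, 0.5,
                  {"protein": 0.20, "fat": 0.08, "sfa": 0.015, "mufa": 0.03,
                   "pufa": 0.03, "magnesium": 0.6, "zinc": 0.015,
                   "phosphorus": 2.2, "iron": 0.01}),
    FoodGroupSpec("oils_nuts", 30, 6.0, 0.85, 0.5,
                  {"fat": 0.55, "mufa": 0.30, "pufa": 0.18, "sfa": 0.07,
                   "fiber": 0.05, "protein": 0.1, "magnesium": 2.0,
                   "phosphorus": 3.0, "zinc": 0.03}),
    FoodGroupSpec("sweets", 70, 4.0, 0.8, 0.5,
                  {"added_sugar": 0.45, "carbohydrate": 0.60, "fat": 0.15,
                   "sfa": 0.08, "alcohol": 0.01}),
    FoodGroupSpec("fast_food", 90, 2.8, 0.5, 0.5,
                  {"protein": 0.10, "fat": 0.15, "sfa": 0.06, "mufa": 0.06,
                   "pufa": 0.02, "carbohydrate": 0.30, "sodium": 0.006,
                   "added_sugar": 0.05}),
]


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 100
    n_days: int = 14
    n_taxa: int = 150
    seq_depth_mean: int = 20000
    food_groups: tuple[FoodGroupSpec, ...] = tuple(DEFAULT_FOOD_GROUPS)
    regularity_range: tuple[float, float] = (20.0, 80.0)  # CV percent
    effect_hei_diversity: float = 0.0    # Shannon bits per diet-score point
    effect_cv_diversity: float = 0.0     # Shannon bits per CV percent point
    stool_coupling: float = 0.0          # prob shift per diet-quality z
    seed: int = 0
    # shaping knobs
    diversity_noise_sd: float = 0.3
    base_diversity: float | None = None  # default: family midpoint
    responder_fraction: float = 0.2
    dirichlet_concentration: float = 2000.0
    low_energy_fraction: float = 0.2     # fraction of days pushed < 1000 kcal
    depth_dispersion: float = 20.0       # NB dispersion of library sizes
    stool_report_prob: float = 0.85

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_days", "n_taxa", "seq_depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.regularity_range
        if not (0 < lo <= hi <= 300):
            raise ValueError("regularity_range must lie within (0, 300] percent")
        if self.dirichlet_concentration <= 0:
            raise ValueError(
                "planted Dirichlet concentration must be positive "
                f"(got {self.dirichlet_concentration})"
            )
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must lie in (0, 1)")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")


@dataclass
class SynthCohort:
    food_log: pd.DataFrame
    feature_table: FeatureTable
    tree: TreeNode
    metadata: pd.DataFrame
    stool_reports: pd.DataFrame
    truth: pd.DataFrame
    responder_taxa: list[str]


def _taxon_ids(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n)]


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted bifurcating tree with positive branch lengths.

    Built by repeated random pairwise joins; leaf labels match the taxa IDs
    used by ``generate_cohort``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=label) for label in _taxon_ids(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        for child in (a, b):
            child.length = float(rng.exponential(0.1) + 0.01)
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return -plogp.sum(axis=-1)


def _build_food_log(config: SynthConfig, rng: np.random.Generator):
    """Vectorised daily-intake draw and long-format food-log assembly."""
    groups = list(config.food_groups)
    n, d, g = config.n_participants, config.n_days, len(groups)
    pids = _participant_ids(n)
    lo, hi = config.regularity_range
    cv_target = rng.uniform(lo, hi, size=n) / 100.0

    mean_g = np.array([fg.mean_g for fg in groups])
    sigma = np.array([fg.sigma_log for fg in groups])
    kcal_per_g = np.array([fg.kcal_per_g for fg in groups])
    eat_prob = np.array([fg.eat_prob for fg in groups])

    part_means = np.exp(
        np.log(mean_g)[None, :] + rng.normal(0.0, 1.0, size=(n, g)) * sigma[None, :]
    )
    shape = (1.0 / cv_target**2)[:, None, None]
    scale = part_means[:, None, :] * (cv_target**2)[:, None, None]
    intake = rng.gamma(np.broadcast_to(shape, (n, d, g)), scale)
    eaten = rng.random((n, d, g)) < eat_prob[None, None, :]
    intake = intake * eaten

    # plant low-energy days to exercise the QC filter
    day_kcal = (intake * kcal_per_g[None, None, :]).sum(axis=2)
    low = rng.random((n, d)) < config.low_energy_fraction
    target_kcal = rng.uniform(400.0, 900.0, size=(n, d))
    factor = np.where(low & (day_kcal > target_kcal), target_kcal / np.maximum(day_kcal, 1e-12), 1.0)
    intake *= factor[:, :, None]

    pi, di, gi = np.nonzero(intake > 0)
    grams = intake[pi, di, gi]
    # occasionally split a group-day into two eating events
    split = rng.random(grams.size) < 0.25
    frac = rng.uniform(0.25, 0.75, size=grams.size)
    g1 = np.where(split, grams * frac, grams)
    g2 = grams * (1 - frac)

    rep_pi = np.concatenate([pi, pi[split]])
    rep_di = np.concatenate([di, di[split]])
    rep_gi = np.concatenate([gi, gi[split]])
    rep_gr = np.concatenate([g1, g2[split]])
    item_no = np.concatenate([np.ones(grams.size, dtype=int),
                              np.full(int(split.sum()), 2, dtype=int)])

    group_names = np.array([fg.name for fg in groups])
    dates = pd.date_range("2021-03-01", periods=d).strftime("%Y-%m-%d").to_numpy()
    density = np.zeros((g, len(NUTRIENT_COLUMNS)))
    for k, fg in enumerate(groups):
        for nut, val in fg.nutrients.items():
            density[k, NUTRIENT_COLUMNS.index(nut)] = val

    log = pd.DataFrame({
        "participant_id": np.array(pids)[rep_pi],
        "date": dates[rep_di],
        "item_id": np.char.add(np.char.add(group_names[rep_gi], "_"),
                               item_no.astype(str)),
        "food_group": group_names[rep_gi],
        "grams": rep_gr,
        "kcal": rep_gr * kcal_per_g[rep_gi],
    })
    nut_vals = rep_gr[:, None] * density[rep_gi]
    for j, nut in enumerate(NUTRIENT_COLUMNS):
        log[nut] = nut_vals[:, j]
    log = log.sort_values(["participant_id", "date", "food_group", "item_id"],
                          kind="mergesort").reset_index(drop=True)
    return log, pids, cv_target


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a full synthetic cohort with planted effects.  Deterministic
    for a fixed config (including seed)."""
    rng_food = substream(config.seed, "foodlog")
    rng_counts = substream(config.seed, "counts")
    rng_stool = substream(config.seed, "stool")
    rng_meta = substream(config.seed, "meta")
    rng_latent = substream(config.seed, "latent")

    log, pids, cv_target = _build_food_log(config, rng_food)
    group_names = [fg.name for fg in config.food_groups]

    # diet-quality latent: the day-wise score downstream analyses will use
    daily = aggregate_daily(log, vocabulary=group_names)
    daily_qc, _ = qc_filter(daily)
    specs = load_component_specs()
    dhei_all, _ = hei_daily(daily, specs)
    if len(daily_qc):
        dhei_qc, _ = hei_daily(daily_qc, specs)
        dhei = dhei_qc.reindex(pids).fillna(dhei_all.reindex(pids))
    else:
        dhei = dhei_all.reindex(pids)
    dhei_v = dhei.to_numpy()

    # one-parameter proportion family: skewed base -> uniform, with the
    # responder block rising monotonically along it
    n_resp = max(1, int(round(config.responder_fraction * config.n_taxa)))
    responder_idx = np.sort(
        rng_counts.choice(config.n_taxa, size=n_resp, replace=False)
    )
    q = rng_counts.lognormal(0.0, 3.0, size=config.n_taxa)
    q[responder_idx] = 1e-8
    q /= q.sum()
    u = rng_counts.lognormal(0.0, 1.0, size=config.n_taxa)
    u /= u.sum()
    t_grid = np.linspace(0.0, 1.0, 513)
    h_grid = _entropy_bits((1 - t_grid)[:, None] * q[None, :] + t_grid[:, None] * u[None, :])
    # entropy is concave along the segment: keep the increasing prefix so the
    # target -> mixture inversion is well defined
    m = int(np.argmax(h_grid))
    t_grid, h_grid = t_grid[: m + 1], h_grid[: m + 1]
    keep = np.concatenate([[True], np.diff(h_grid) > 1e-12])
    t_grid, h_grid = t_grid[keep], h_grid[keep]

    base = config.base_diversity
    if base is None:
        base = float(np.interp(0.5, t_grid, h_grid))
    cv_pct = cv_target * 100.0
    latent = (
        base
        + config.effect_hei_diversity * (dhei_v - dhei_v.mean())
        + config.effect_cv_diversity * (cv_pct - cv_pct.mean())
        + rng_latent.normal(0.0, config.diversity_noise_sd, size=len(pids))
    )
    latent_clipped = np.clip(latent, h_grid[0] + 1e-3, h_grid[-1] - 1e-3)
    t_i = np.interp(latent_clipped, h_grid, t_grid)
    p_i = (1 - t_i)[:, None] * q[None, :] + t_i[:, None] * u[None, :]

    alpha = config.dirichlet_concentration * p_i
    if (alpha < 0).any():
        raise ValueError("planted concentrations became negative; adjust effects")
    gam = rng_counts.standard_gamma(alpha)
    pvec = gam / gam.sum(axis=1, keepdims=True)
    r = config.depth_dispersion
    depth = rng_counts.negative_binomial(r, r / (r + config.seq_depth_mean),
                                         size=len(pids))
    depth = np.maximum(depth, 1000)
    counts = np.empty((len(pids), config.n_taxa), dtype=np.int64)
    for i in range(len(pids)):
        counts[i] = rng_counts.multinomial(depth[i], pvec[i])
    table = FeatureTable(pd.DataFrame(counts, index=pids, columns=_taxon_ids(config.n_taxa)))

    tree = generate_tree(config.n_taxa, substream_seed(config.seed, "tree"))

    age = np.clip(np.round(rng_meta.normal(45, 13, len(pids))), 18, 75).astype(int)
    bmi = np.round(np.clip(rng_meta.normal(24.0, 3.5, len(pids)), 16.0, 45.0), 1)
    bmi_cat = pd.cut(bmi, [0, 18.5, 25, 30, np.inf],
                     labels=["underweight", "normal", "overweight", "obese"],
                     right=False).astype(str)
    metadata = pd.DataFrame({
        "participant_id": pids,
        "age": age,
        "bmi": bmi,
        "bmi_category": bmi_cat,
        "gender": rng_meta.choice(["female", "male"], size=len(pids)),
        "smoking": rng_meta.choice(["never", "former", "current"],
                                   p=[0.6, 0.25, 0.15], size=len(pids)),
        "defecation_frequency": np.round(rng_meta.lognormal(np.log(1.2), 0.4,
                                                            len(pids)), 2),
        "hunger": rng_meta.integers(1, 11, size=len(pids)),
    })

    stool_reports = _draw_stool(config, rng_stool, pids, dhei_v)

    truth = pd.DataFrame({
        "participant_id": pids,
        "target_cv_pct": cv_pct,
        "diet_quality_latent": dhei_v,
        "diversity_latent": latent_clipped,
        "mixture_t": t_i,
    })
    return SynthCohort(
        food_log=log,
        feature_table=table,
        tree=tree,
        metadata=metadata,
        stool_reports=stool_reports,
        truth=truth,
        responder_taxa=[_taxon_ids(config.n_taxa)[i] for i in responder_idx],
    )


def _draw_stool(config, rng, pids, dhei_v):
    sd = dhei_v.std()
    z = (dhei_v - dhei_v.mean()) / sd if sd > 0 else np.zeros_like(dhei_v)
    base = np.array([0.25, 0.55, 0.08, 0.12])  # great, normal, constipated, diarrhea
    p_great = np.clip(base[0] + config.stool_coupling * z, 0.02, 0.90)
    p_diar = np.clip(base[3] - config.stool_coupling * z, 0.01, 0.90)
    rest = np.clip(1.0 - p_great - p_diar, 1e-6, None)
    p_norm = rest * base[1] / (base[1] + base[2])
    p_con = rest * base[2] / (base[1] + base[2])
    probs = np.stack([p_great, p_norm, p_con, p_diar], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    cats = np.array(["great", "normal", "constipated", "diarrhea"])

    dates = pd.date_range("2021-03-01", periods=config.n_days).strftime("%Y-%m-%d")
    reported = rng.random((len(pids), config.n_days)) < config.stool_report_prob
    draws = rng.random((len(pids), config.n_days))
    cum = probs.cumsum(axis=1)
    cat_idx = (draws[:, :, None] > cum[:, None, :]).sum(axis=2)
    pi, di = np.nonzero(reported)
    return pd.DataFrame({
        "participant_id": np.array(pids)[pi],
        "date": dates.to_numpy()[di],
        "category": cats[cat_idx[pi, di]],
    })


def write_cohort(cohort: SynthCohort, outdir: str | Path, biom: bool = False) -> dict[str, Path]:
    """Write all cohort artifacts as text files (TSV + Newick).

    With ``biom=True`` additionally writes a BIOM v2.1 feature table
    (requires the optional biom-format dependency).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "food_log": outdir / "food_log.tsv",
        "metadata": outdir / "metadata.tsv",
        "stool": outdir / "stool.tsv",
        "feature_table": outdir / "feature_table.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.tsv",
    }
    cohort.food_log.to_csv(paths["food_log"], sep="\t", index=False)
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.stool_reports.to_csv(paths["stool"], sep="\t", index=False)
    cohort.feature_table.to_tsv(paths["feature_table"])
    write_newick(cohort.tree, paths["tree"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if biom:
        import biom as biom_mod
        import h5py

        bt = biom_mod.Table(
            cohort.feature_table.data.to_numpy().T,
            observation_ids=cohort.feature_table.taxon_ids,
            sample_ids=cohort.feature_table.sample_ids,
        )
        paths["biom"] = outdir / "feature_table.biom"
        with h5py.File(paths["biom"], "w") as fh:
            bt.to_hdf5(fh, "dietrhythm synth")
    return paths
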