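import numpy as np
import pandas as pd
import pytest

from dietrhythm import assoc, dietmetrics, foodlog, micro, synth


@pytest.fixture(scope="session")
def specs():
    return dietmetrics.load_component_specs()


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with planted diet-quality, regularity and stool effects."""
    cfg = synth.SynthConfig(
        n_participants=150,
        n_days=12,
        n_taxa=60,
        seq_depth_mean=5000,
        seed=11,
        effect_hei_diversity=0.03,
        effect_cv_diversity=-0.012,
        stool_coupling=0.10,
    )
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_frame(planted_cohort):
    """Merged cohort frame for the planted cohort."""
    daily = foodlog.aggregate_daily(planted_cohort.food_log)
    daily, _ = foodlog.qc_filter(daily)
    profile = dietmetrics.build_diet_profile(daily)
    alpha = micro.alpha_metrics(planted_cohort.feature_table, tree=planted_cohort.tree)
    frame, _ = assoc.build_cohort_frame(profile, alpha, planted_cohort.metadata)
    return frame


def make_ideal_menu(n_participants: int = 1, energy: float = 2000.0) -> pd.DataFrame:
    """One-day menu saturating every shipped HEI-2020 adequacy standard and
    sitting below every moderation full-score threshold."""
    row = {
        "vegetables": 330.0,          # with greens: 390/150/2 = 1.3 cup/1000
        "greens_beans": 60.0,         # 0.2 cup/1000
        "fruits": 240.0,              # 0.8 cup/1000; whole 0.4
        "whole_grains": 84.0,         # 1.5 oz/1000
        "refined_grains": 0.0,
        "dairy": 637.0,               # 1.3 cup/1000
        "meat": 100.0,
        "seafood_plant_proteins": 50.0,
        "oils_nuts": 10.0,
        "mufa": 20.0,
        "pufa": 15.0,
        "sfa": 10.0,                  # ratio 3.5; 4.5% of energy
        "sodium": 0.5,
        "added_sugar": 10.0,          # 2% of energy
        "energy_kcal": energy,
    }
    frames = []
    for i in range(n_participants):
        frames.append({"participant_id": f"P{i:03d}", "date": "2021-01-01", **row})
    return pd.DataFrame(frames)


def make_worst_menu(energy: float = 2000.0) -> pd.DataFrame:
    """Menu scoring zero on every component: no adequacy intake, every
    moderation density at or past its zero-score threshold."""
    return pd.DataFrame([{
        "participant_id": "P000", "date": "2021-01-01",
        "vegetables": 0.0, "greens_beans": 0.0, "fruits": 0.0,
        "whole_grains": 0.0, "dairy": 0.0, "meat": 0.0,
        "seafood_plant_proteins": 0.0, "oils_nuts": 0.0,
        "refined_grains": 250.0,   # 4.46 oz/1000 > 4.3
        "mufa": 0.0, "pufa": 0.0, "sfa": 40.0,  # 18% energy > 16; ratio 0 < 1.2
        "sodium": 4.5,             # 2.25 g/1000 > 2.0
        "added_sugar": 140.0,      # 28% energy > 26
        "energy_kcal": energy,
    }])
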