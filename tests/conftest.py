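import numpy as np
import pandas as pd
import pytest

from iezmeta.data_model import COLUMNS
from iezmeta.synthetic_data import SimulationConfig, simulate_dataset


def make_comparisons(rows: list[dict]) -> pd.DataFrame:
    """Build a comparisons table from sparse row dicts with sane defaults."""
    defaults = {
        "comparison_id": None, "source_id": "s1", "study_id": "s1_a",
        "species_id": "sp1", "taxon_group": "mammal", "clade": "carnivora",
        "distance_m": 10.0, "infra_type": "paved_road", "habitat": "closed",
        "mean_treat": 4.0, "sd_treat": 2.0, "n_treat": 5,
        "mean_ctrl": 5.0, "sd_ctrl": 2.0, "n_ctrl": 5,
        "scale_D": 1.0, "body_mass_g": 100.0, "diet_pct": 0.0,
        "quality_a": 1, "quality_b": 1,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        if rec["comparison_id"] is None:
            rec["comparison_id"] = f"c{i}"
        out.append(rec)
    return pd.DataFrame(out, columns=list(COLUMNS))


@pytest.fixture(scope="session")
def small_sim():
    """A small reptile dataset with full hierarchy and known truth."""
    cfg = SimulationConfig(
        seed=7, taxon_group="reptile", n_sources=6, site_cv=0.5,
        within_site_n=(4, 8), sd_missing_rate=0.2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_effect_set(small_sim):
    from iezmeta.effect_sizes import build_effect_size_set, impute_sd
    df = impute_sd(small_sim.comparisons, "poisson")
    return build_effect_size_set(df)
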