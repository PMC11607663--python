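import pandas as pd
import pytest

from lipidqa.adducts import SpeciesAdductProfile
from lipidqa.simulate import SimulationConfig, simulate_database, simulate_run, simulate_runs


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_db(sim_config):
    db, truth = simulate_database(sim_config)
    return db, truth


@pytest.fixture(scope="session")
def sim_batch(sim_config, sim_db):
    db, _ = sim_db
    runs, feature_truth = simulate_runs(sim_config and db, sim_config, n_samples=2, n_blanks=1)
    return runs, feature_truth


def profiles_from_truth(feature_truth: pd.DataFrame, polarity: str = "+"):
    """Ground-truth adduct profiles for consensus building."""
    profiles = []
    sub = feature_truth
    if "sample_id" in sub.columns:
        sub = sub[sub["sample_id"] == sub["sample_id"].iloc[0]]
    for (name, subclass), grp in sub.groupby(["name", "subclass"]):
        obs = [
            (r["adduct"], r["observed_mz"], r["rt"], r["area"])
            for _, r in grp.iterrows()
        ]
        profiles.append(
            SpeciesAdductProfile(name, polarity, obs, 0.0, subclass=subclass)
        )
    return profiles


@pytest.fixture(scope="session")
def pos_profiles(sim_config, sim_db):
    db, _ = sim_db
    _, truth = simulate_run(db, sim_config, "P1", polarity="+")
    return profiles_from_truth(truth)
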