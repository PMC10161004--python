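import numpy as np
import pandas as pd
import pytest

from forestcti import (
    SimulationConfig,
    generate_landscape,
    generate_species_pool,
    generate_tree_censuses,
)


@pytest.fixture(scope="session")
def base_config():
    return SimulationConfig(n_plots=50, n_species=20, seed=7)


@pytest.fixture(scope="session")
def landscape(base_config):
    return generate_landscape(base_config)


@pytest.fixture(scope="session")
def species_pool(base_config):
    return generate_species_pool(base_config)


@pytest.fixture(scope="session")
def censuses(landscape, species_pool, base_config):
    return generate_tree_censuses(landscape, species_pool, base_config)


@pytest.fixture(scope="session")
def trees(censuses):
    return censuses[0]


@pytest.fixture(scope="session")
def seedlings(censuses):
    return censuses[1]


@pytest.fixture(scope="session")
def index_map(species_pool):
    # true optima double as a perfectly known species temperature index
    return species_pool.set_index("species_id")["true_optimum"]


def random_community(rng, n_species=5, max_trees=10):
    """One random subplot community for oracle tests."""
    n = rng.integers(1, max_trees + 1)
    return pd.DataFrame(
        {
            "species_id": rng.integers(0, n_species, n),
            "dbh": rng.uniform(12.7, 80.0, n),
        }
    )


def make_trees(rows):
    """Small literal tree tables for scenario tests."""
    df = pd.DataFrame(
        rows,
        columns=[
            "tree_id", "plot_id", "subplot_id", "species_id",
            "dbh_t1_cm", "dbh_t2_cm", "dist_m", "fate", "size_class",
        ],
    )
    return df.astype({"dbh_t1_cm": float, "dbh_t2_cm": float, "dist_m": float})


def random_subplot_trees(rng, plot_id=0, subplot_id=0, n_species=6):
    """Random subplot with survivors, deaths and recruits for identity tests."""
    rows = []
    tid = 0
    for _ in range(rng.integers(1, 9)):
        fate = rng.choice(["survivor", "died", "recruit"], p=[0.6, 0.25, 0.15])
        d1 = rng.uniform(12.7, 60.0)
        growth = rng.uniform(-1.0, 6.0)  # negative measured growth allowed
        rows.append(
            dict(
                tree_id=tid,
                plot_id=plot_id,
                subplot_id=subplot_id,
                species_id=int(rng.integers(0, n_species)),
                dbh_t1_cm=np.nan if fate == "recruit" else d1,
                dbh_t2_cm=(
                    np.nan if fate == "died"
                    else (12.7 + rng.uniform(0, 2) if fate == "recruit"
                          else max(d1 + growth, 12.7))
                ),
                dist_m=rng.uniform(0, 7.32),
                fate=fate,
                size_class="main",
            )
        )
        tid += 1
    return pd.DataFrame(rows)
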