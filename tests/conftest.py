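import pandas as pd
import pytest

from rbai import growth
from rbai.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down but structurally complete monitoring network."""
    return SimulationConfig(n_plots=25, seed=1234, grid_spacing_deg=0.25)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_increments(small_dataset):
    incr = growth.compute_increments(small_dataset["trees"])
    return growth.assign_circ_classes(incr)


@pytest.fixture()
def tiny_trees():
    """Three trees, hand-written circumference series."""
    rows = []
    for tid, series in [
        ("T1", {2000: 100.0, 2001: 102.0, 2002: 104.0}),
        ("T2", {2000: 50.0, 2001: 51.0, 2003: 53.0}),   # gap at 2002
        ("T3", {2000: 80.0, 2001: 80.0, 2002: 80.0}),   # no growth
    ]:
        for year, c in series.items():
            rows.append({"plot_id": "P1", "tree_id": tid, "species": "FS",
                         "year": year, "circumference_cm": c})
    return pd.DataFrame(rows)
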