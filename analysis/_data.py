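"""Shared helpers for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

from rbai.io import write_table
from rbai.synthetic import SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"
SEED = 20231206


def ensure_dataset(seed: int = SEED) -> dict[str, pd.DataFrame]:
    """Load the simulated network tables, generating them if absent."""
    if not (DATA / "trees.csv").exists():
        cfg = SimulationConfig(seed=seed)
        tables = simulate_dataset(cfg)
        for name, df in tables.items():
            write_table(df, DATA / f"{name}.csv")
    return {p.stem: pd.read_csv(p) for p in DATA.glob("*.csv")}
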