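import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tissuenet import SampleSheet, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """500-gene dataset with planted DE, TS and rewired regulators."""
    cfg = SimConfig(
        n_genes=500,
        n_de=50,
        de_shift=2.0,
        de_frac_down=0.5,
        n_ts=30,
        ts_boost=5.0,
        n_regulators=20,
        n_rewired_regulators=2,
        rewire_strength=1.0,
        n_targets_per_regulator=10,
        n_snps=60,
        seed=7,
        variance_components=(1.0, 0.3, 0.05, 0.005, 0.2),
        baseline_mean=8.0,
    )
    mat, sheet, truth = generate_dataset(cfg)
    return cfg, mat, sheet, truth


@pytest.fixture
def tiny_sheet():
    """2 tissues x 2 states x 2 animals per state, 8 libraries."""
    rows = []
    for state, animals in (("PRE", ["A1", "A2"]), ("POST", ["A3", "A4"])):
        for a in animals:
            for t in ("T1", "T2"):
                rows.append(
                    {"library": f"{t}_{state}_{a}", "tissue": t, "animal": a, "state": state}
                )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
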