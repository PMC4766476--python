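import numpy as np
import pandas as pd
import pytest

from redoxscreen import gen_counts, select_groups
from redoxscreen.simulate import CountsSimConfig


@pytest.fixture(scope="session")
def counts_sim():
    """One default synthetic count matrix with planted groups (seed 1)."""
    return gen_counts(seed=1)


@pytest.fixture(scope="session")
def selection(counts_sim):
    counts, design, truth = counts_sim
    return select_groups(counts, design)


@pytest.fixture(scope="session")
def null_sim():
    """A matrix with no planted structure (background + housekeeping only)."""
    cfg = CountsSimConfig(n_group_a=0, n_group_b=0)
    return gen_counts(cfg, seed=11)


def make_screen_plate(ratios, plate_id="P1", control_roles=None):
    """Single-plate well table with unit renilla, so ratio == fluc."""
    ratios = list(ratios)
    roles = control_roles or ["none"] * len(ratios)
    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "well_id": [f"A{i + 1:02d}" for i in range(len(ratios))],
            "gene_id": [f"g{i + 1}" for i in range(len(ratios))],
            "dsrna_id": [f"g{i + 1}_ds1" for i in range(len(ratios))],
            "fluc": np.asarray(ratios, dtype=float),
            "rluc": 1.0,
            "control_role": roles,
        }
    )
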