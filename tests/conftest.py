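import warnings

import numpy as np
import pandas as pd
import pytest

from hypomir import RunConfig, SimulationConfig, Thresholds

# lifelines emits convergence chatter on tiny fixtures; keep test output readable
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """A scaled-down simulation for fast structural/unit tests."""
    return SimulationConfig(
        seed=7, n_target_features=96, n_planted_induced=12,
        n_signature_pos=4, n_signature_neg=4, n_unexpressed=2,
        cohort_n=120, anchor_gene_count=30, n_background_genes=20,
        trial_n_per_arm=60,
    )


@pytest.fixture(scope="session")
def fast_run_config(small_sim_config):
    """Reduced end-to-end configuration (smaller forest/iteration budget)."""
    return RunConfig(
        seed=7,
        simulation=small_sim_config,
        thresholds=Thresholds(boruta_n_trees=100, boruta_max_iter=60),
    )


def toy_ct_table(records):
    """Build a Ct table from (cell_line, o2, rep, feature, cls, ct) tuples."""
    return pd.DataFrame.from_records(
        records,
        columns=["cell_line", "o2_percent", "replicate", "feature_id",
                 "feature_class", "ct"],
    )


@pytest.fixture
def make_ct_table():
    return toy_ct_table


@pytest.fixture
def single_line_table():
    """One cell line, 2 conditions x 3 replicates: 1 control + 2 targets.

    Target A is induced (Ct lower by 1.5 under hypoxia), target B is flat.
    Noise-free so downstream quantities are exact.
    """
    rows = []
    for o2, shift in ((21.0, 0.0), (0.2, 1.5)):
        for rep in (1, 2, 3):
            rows.append(("CL1", o2, rep, "CTRL-01", "control", 16.0))
            rows.append(("CL1", o2, rep, "miR-A", "target", 25.0 - shift))
            rows.append(("CL1", o2, rep, "miR-B", "target", 24.0))
    return toy_ct_table(rows)
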