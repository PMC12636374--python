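import numpy as np
import pandas as pd
import pytest

from screensuite import fixtures as fx


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_state_pdb(tmp_path_factory):
    """15-model two-state ensemble with one planted outlier (0.87/0.13,
    6 A hinge separation, 0.5 A noise)."""
    spec = fx.EnsembleSpec(
        n_models=15,
        n_residues=40,
        cluster_occupancies=(0.87, 0.13),
        inter_cluster_shift=6.0,
        noise_sigma=0.5,
        n_outliers=1,
        outlier_shift=50.0,
        seed=7,
    )
    text, truth = fx.make_two_state_ensemble(spec)
    path = tmp_path_factory.mktemp("ens") / "two_state.pdb"
    path.write_text(text)
    return path, truth


@pytest.fixture
def small_score_table():
    """Hand-checkable 4-row table (the Pareto worked example)."""
    return pd.DataFrame(
        {
            "compound_id": ["A", "B", "C", "D"],
            "gscore": [-10.0, -9.0, -8.0, -10.0],
            "dg_bind": [-60.0, -65.0, -50.0, -50.0],
        }
    )
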