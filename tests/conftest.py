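import numpy as np
import pandas as pd
import pytest

from spruceqtl import synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SimConfig(n_transcripts=60)


@pytest.fixture(scope="session")
def study(default_config):
    """One simulated study shared across tests: map, genotypes, traits."""
    rng = np.random.default_rng(11)
    map_df, tms, cross_df = synth.simulate_pedigree(default_config, rng)
    truth = synth.default_architecture(
        map_df, default_config, rng, n_cis=10, n_trans=10, n_hotspot=20
    )
    expr, pheno, truth = synth.simulate_traits(map_df, tms, truth, default_config, rng)
    return {
        "config": default_config,
        "map": map_df,
        "transmissions": tms,
        "cross_df": cross_df,
        "truth": truth,
        "expression": expr,
        "phenotypes": pheno,
    }


@pytest.fixture()
def two_class_codes():
    """Transmission codes splitting 8 progeny 4/4."""
    return np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=float)


@pytest.fixture()
def tiny_map():
    return pd.DataFrame(
        {
            "marker": ["M1", "M2", "M3", "M4"],
            "lg": [1, 1, 1, 2],
            "cm": [0.0, 4.0, 6.0, 0.0],
        }
    )
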