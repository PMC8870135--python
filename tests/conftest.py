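import pandas as pd
import pytest

from sslscreen import model, simulate


@pytest.fixture(scope="session")
def mini_config():
    """A small but structurally complete screen (fast to simulate)."""
    return simulate.SimulationConfig(n_genes=24, n_interactors=3, seed=11)


@pytest.fixture(scope="session")
def mini_screen(mini_config):
    return simulate.simulate_screen(mini_config)


@pytest.fixture(scope="session")
def mini_library(mini_config):
    return simulate.default_library(
        mini_config.n_genes, mini_config.sirnas_per_gene
    )


@pytest.fixture(scope="session")
def default_screen():
    """One full-size default screen (207 genes), shared across tests."""
    cfg = simulate.SimulationConfig(seed=7)
    measurements, truth = simulate.simulate_screen(cfg)
    return cfg, measurements, truth


@pytest.fixture
def tiny_library():
    return model.SiRNALibrary(
        pd.DataFrame({
            "sirna_id": ["g1_s1", "g1_s2", "g1_s3", "g2_s1", "g2_s2", "g2_s3"],
            "gene": ["G1"] * 3 + ["G2"] * 3,
        })
    )
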