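import numpy as np
import pytest

from ms2struct.autoencoder import AEConfig, train_autoencoder
from ms2struct.simulate import SimConfig, build_dataset, generate_library


@pytest.fixture(scope="session")
def small_library():
    """300 distinct toy molecules, deterministic."""
    return generate_library(SimConfig(n_molecules=300, max_heavy_atoms=16, seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Full dataset (spectra + splits) over 250 molecules."""
    return build_dataset(SimConfig(n_molecules=250, max_heavy_atoms=16, seed=7))


@pytest.fixture(scope="session")
def tiny_ae(small_library):
    """A lightly trained AE: enough signal for contract tests, fast."""
    config = AEConfig(
        d_embed=32, hidden_size=96, token_embed_dim=32, epochs=25, seed=3,
        lr=3e-3, lr_final=1e-3,
    )
    model, log = train_autoencoder(small_library[:150], config)
    return model, log, small_library[:150]
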