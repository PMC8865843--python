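import numpy as np
import pytest

from hapticode import autoencoder as ae
from hapticode import preprocessing as pp
from hapticode import synthetic as syn


@pytest.fixture(scope="session")
def small_library():
    """7 categories x 2 materials, window-coherent narrow spectral peaks."""
    return syn.make_material_library(7, [2] * 7, seed=11, bump_width=(1.5, 4.0))


@pytest.fixture(scope="session")
def participants():
    return syn.make_participants(3, seed=7)


@pytest.fixture(scope="session")
def small_segments(small_library, participants):
    """Normalized train/test segments from a miniature synthetic study."""
    recs = syn.synth_dataset(
        small_library, participants[:2], duration_s=0.4, rate_hz=3200.0, seed=11
    )
    full = pp.segment_recordings(recs)
    train, test = pp.split(full, train_fraction=0.9, seed=11)
    train_n, test_n, full_n, norm = pp.normalize(train, test, full)
    return {"train": train_n, "test": test_n, "full": full_n, "normalizer": norm}


@pytest.fixture(scope="session")
def tiny_model(small_segments):
    """A small trained autoencoder shared across tests (d=8, short training)."""
    return ae.ConvAutoencoder(
        latent_dim=8, epochs=8, batch_size=16, learning_rate=2e-3, random_state=0
    ).fit(small_segments["train"], validation=small_segments["test"])
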