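import numpy as np
import pytest

from ecgbeats import nn_core, synth
from ecgbeats.records import beats_to_array


@pytest.fixture(scope="session")
def tiny_dataset():
    """Clean 30-beats-per-class dataset shared across fast tests."""
    spec = synth.DatasetSpec(counts={c: 30 for c in "ALNRV"}, scale=1.0, seed=42)
    records, beats = synth.generate_dataset(spec)
    return records, beats


@pytest.fixture(scope="session")
def tiny_bank(tiny_dataset):
    """A very small trained autoencoder bank (fast, for API-level tests)."""
    from ecgbeats import models

    _, beats = tiny_dataset
    x, y = beats_to_array(beats)
    by_class = {c: x[y == c] for c in "ALNRV"}
    cfg = nn_core.TrainingConfig(epochs=4, batch_size=32, patience=3, seed=0)
    ae = models.AutoencoderConfig(encoder_units=(8, 4))
    return models.train_autoencoder_bank(by_class, cfg, ae), (x, y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
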