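import numpy as np
import pytest

from kdemg.pipeline import ExperimentConfig
from kdemg.signal_io import WindowSpec
from kdemg.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_seq_config():
    """A small, fast sequential-experiment config used by pipeline tests.

    Sliding windows give each class enough feature rows (4 per repetition)
    for the correlation estimates in CFS to have resolution; with one window
    per repetition the discretized correlations saturate and the search
    degenerates to a singleton subset.
    """
    return ExperimentConfig(
        synthetic=SyntheticConfig(
            n_classes=4, n_channels=6, n_repetitions=6,
            fs=1000.0, contraction_s=1.5, band=(20.0, 450.0),
            snr_db=20.0, profile_seed=7, noise_seed=11,
        ),
        filter_band=(20.0, 450.0),
        window=WindowSpec(width_ms=400.0, step_ms=300.0, mode="sliding"),
        n_grid=512,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_records(tiny_seq_config):
    return generate_dataset(tiny_seq_config.synthetic)
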