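"""Shared fixtures: small synthetic datasets and a tiny network config."""

from __future__ import annotations

import numpy as np
import pytest

from pulsebp import NetworkConfig, SynthConfig, generate_dataset, standard_corruption
from pulsebp.preprocess import preprocess_record


@pytest.fixture(scope="session")
def clean_dataset():
    """Three clean subjects, 60 s each, at the default physiology."""
    cfg = SynthConfig(n_subjects=3, record_seconds=60.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_segments(clean_dataset):
    records, _ = clean_dataset
    return [seg for rec in records for seg in preprocess_record(rec)]


@pytest.fixture(scope="session")
def corrupt_dataset():
    """One subject carrying the standard corruption fixture."""
    cfg = SynthConfig(
        n_subjects=1, record_seconds=160.0, corruption=standard_corruption(), seed=13
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_net_config():
    """A scaled-down architecture for gradient checks (float64, no dropout)."""
    return NetworkConfig(
        n=4,
        dropout_rate=0.0,
        hidden_units=3,
        input_len=20,
        conv_layers=((4, 2), (2, 4)),
        pool_size=2,
        dtype="float64",
        init_output=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
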