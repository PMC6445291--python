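import numpy as np
import pytest

from laminar_encoding import pipeline as pl
from laminar_encoding import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sounds():
    """24 synthetic sounds (4 per category), split into 4 balanced sets."""
    return sd.split_sets(sd.make_sounds(4, seed=2), 4, seed=3)


@pytest.fixture(scope="session")
def small_designs(small_sounds):
    return sd.make_design(small_sounds, runs=12, seed=5)


@pytest.fixture(scope="session")
def full_sounds():
    """The full-size stimulus set: 144 sounds, 24 per category, 4 sets."""
    return sd.split_sets(sd.make_sounds(24, seed=11), 4, seed=12)


@pytest.fixture(scope="session")
def full_features(full_sounds):
    """Feature matrices of both models for the 144-sound set."""
    from laminar_encoding import audio_features as af

    return {
        tag: af.build_feature_matrix(full_sounds, tag)
        for tag in ("frequency", "modulation")
    }


@pytest.fixture(scope="session")
def reduced_config():
    """The reduced-size replicate protocol used for end-to-end checks:
    72 sounds (12/category), 4 grid points per region x 9 depths,
    12 hemispheres, full BOLD response path."""
    return pl.PipelineConfig(
        n_per_category=12,
        n_units=12,
        n_voxels_per_cell=4,
        scenario="default",
        response_path="bold",
        seed=73,
    )


@pytest.fixture(scope="session")
def reduced_bundle(reduced_config):
    return pl.prepare_stimuli(reduced_config, reduced_config.seed)
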