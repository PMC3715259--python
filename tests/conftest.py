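import numpy as np
import pytest

from geomexpr import GenConfig, LandmarkSequence, default_class_models, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, L=5, F=9, scale=10.0, label=None, sequence_id="seq"):
    return LandmarkSequence(
        coords=rng.normal(0.0, scale, size=(L, F, 2)),
        label=label,
        sequence_id=sequence_id,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Compact 6-class dataset from the generator (fast to fit)."""
    cfg = GenConfig(n_per_class=8, frame_range=(7, 24), seed=11)
    return generate_dataset(default_class_models(cfg.L), cfg)
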