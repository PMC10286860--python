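import pytest

from pediecg import beat_classifier as bc
from pediecg.datasets import make_beat_image_dataset
from pediecg.synthetic import generate_cohort


@pytest.fixture(scope="session")
def cohort20():
    """Seeded default-noise cohort used by the segmentation suite."""
    return generate_cohort(20, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but learnable 4-class beat-image dataset."""
    return make_beat_image_dataset(n_per_class=40, seed=11)


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A quickly trained linear CNN for pipeline/CLI tests."""
    spec = bc.ModelSpec(family="linear")
    config = bc.TrainConfig(seed=3, max_epochs=4, early_stop_patience=4)
    return bc.train(bc.build_model(spec, config), small_dataset, config)
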