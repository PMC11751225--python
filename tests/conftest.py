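import numpy as np
import pytest

from eegshrink import (
    DrowsinessClassifier, ModelConfig, SyntheticSpec, TrainConfig,
    generate_dataset,
)


@pytest.fixture
def tiny_config():
    """Small architecture for fast structural and gradient tests."""
    return ModelConfig(input_len=32, conv_kernel=8, conv_stride=2,
                       conv_pad=3, n_filters=4, se_reduction=2,
                       dropout_p=0.3)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic study conditions: 8 subjects x 200 epochs."""
    return generate_dataset(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def trained(default_dataset):
    """One model trained on subjects 1-7 of the default synthetic set.

    Shared by the interpretation and saliency tests; subject 0 is the
    held-out evaluation subject.
    """
    train_set = default_dataset.without_subject(0)
    clf = DrowsinessClassifier(train_set, ModelConfig(),
                               TrainConfig(seed=0, n_epochs=10))
    res = clf.fit()
    return res, default_dataset.for_subject(0)
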