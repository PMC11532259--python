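"""Shared fixtures: small synthetic datasets and a desk-scale trained model."""

from __future__ import annotations

import numpy as np
import pytest

from frcnn.model import FrCNNClassifier
from frcnn.synth import SyntheticSpec, generate, split

# widths of the reduced network used for desk-scale training experiments
DESK_CONV = (4, 4)
DESK_DENSE = (16, 8)


@pytest.fixture(scope="session")
def small_batch():
    """120 images (40/class) at 32x32, quick to generate and train on."""
    return generate(SyntheticSpec(n_per_class=40, image_shape=(32, 32, 1), seed=7))


@pytest.fixture(scope="session")
def small_splits(small_batch):
    return split(small_batch, seed=7)


@pytest.fixture(scope="session")
def trained_classifier():
    """A desk-scale classifier trained to high accuracy on 64x64 images.

    Shared by the explanation tests; 300 images/class and 20 epochs at
    the recommended fractional order reach perfect validation accuracy
    on the synthetic task.
    """
    batch = generate(SyntheticSpec(n_per_class=300, seed=11))
    clf = FrCNNClassifier(
        alpha=1.5, learning_rate=0.001, conv_filters=DESK_CONV,
        dense_units=DESK_DENSE, epochs=20, batch_size=32, random_state=11,
    )
    clf.fit(batch.values.astype(np.float32), batch.labels)
    return clf
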