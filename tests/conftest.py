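import numpy as np
import pytest

from tailbcs import (
    BCSClassifier,
    SyntheticSpec,
    generate_arrays,
    load_arrays,
    split_dataset,
)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(n_per_class=100, seed=42)


@pytest.fixture(scope="session")
def corpus(default_spec):
    """Full synthetic corpus (images, bboxes, labels) at default conditions."""
    return generate_arrays(default_spec)


@pytest.fixture(scope="session")
def cropped_splits(corpus):
    """Tail-cropped 32px inputs split 7:2:1, as (train, val, test) pairs."""
    images, bboxes, labels = corpus
    x, y = load_arrays(None, input_size=32, images=images, bboxes=bboxes,
                       labels=labels)
    sp = split_dataset(len(x), seed=42)
    return (
        (x[sp.train], y[sp.train]),
        (x[sp.val], y[sp.val]),
        (x[sp.test], y[sp.test]),
    )


@pytest.fixture(scope="session")
def trained_tiny(cropped_splits):
    """A small CNN trained on the synthetic corpus (shared across tests)."""
    train, val, _ = cropped_splits
    clf = BCSClassifier(backbone="tiny", max_epochs=20, seed=42)
    clf.fit(*train, X_val=val[0], y_val=val[1])
    return clf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
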