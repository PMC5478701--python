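import numpy as np
import pytest

from erbp import ErbpClassifier, PresentationProtocol, RateClassifier
from erbp.datasets import PrototypeTaskSpec, make_prototype_task


@pytest.fixture(scope="session")
def task():
    """The default desk-scale prototype task (64 features, 3 classes)."""
    return make_prototype_task(PrototypeTaskSpec())


@pytest.fixture(scope="session")
def micro_task():
    """A tiny task for fast protocol-level tests."""
    return make_prototype_task(
        PrototypeTaskSpec(n_classes=2, n_features=16, n_train=6, n_test=6,
                          seed=3)
    )


@pytest.fixture(scope="session")
def fast_protocol():
    """Short presentations for unit-level network tests."""
    return PresentationProtocol(sample_duration=100.0, learn_gate_delay=20.0,
                                test_duration=100.0)


@pytest.fixture(scope="session")
def trained_fit(task):
    """Spiking classifier trained for 20 epochs with per-epoch snapshots.

    Shared by the end-to-end learning, alignment and inference-invariance
    checks; training dominates the suite runtime so it runs once.
    """
    train, test = task
    model = ErbpClassifier(train, hidden=(32,))
    return model.fit(epochs=20, seed=1, test_data=test, snapshot_every=1)


@pytest.fixture(scope="session")
def rate_rbp_fit(task):
    """Rate-model direct-RBP reference trained on the same task."""
    train, test = task
    return RateClassifier(train, hidden=(32,), rule="rbp").fit(
        epochs=20, seed=1, test_data=test
    )
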