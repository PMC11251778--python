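import numpy as np
import pytest

from qcpattern.synth import DEFAULT_BASE_CATCHES, solve_element_catches
from qcpattern.vision import ConeCatchImage, VisualSystem


@pytest.fixture(scope="session")
def vs():
    """Default triggerfish visual system (1:2:2:2, noise 0.05, 3 cpd, thresholds 2/4)."""
    return VisualSystem()


@pytest.fixture(scope="session")
def base_catches():
    return np.array(DEFAULT_BASE_CATCHES)


@pytest.fixture
def two_patch(vs, base_catches):
    """Factory: noise-free image of two homogeneous patches at exact ΔS / ΔL."""

    def make(ds, dl, shape=(10, 16)):
        elem = solve_element_catches(base_catches, ds, dl, vs)
        catches = np.ones(shape + (4,)) * base_catches
        catches[:, shape[1] // 2:, :] = elem
        return ConeCatchImage(catches, np.ones(shape, bool), 2.0, "two_patch")

    return make


def label_image(labels, catch_map, px_per_mm=1.0):
    """Build a ConeCatchImage whose pixel catches encode an integer label map."""
    labels = np.asarray(labels)
    H, W = labels.shape
    catches = np.zeros((H, W, 4))
    for lab, q in catch_map.items():
        catches[labels == lab] = q
    mask = labels > 0
    return ConeCatchImage(catches, mask, px_per_mm)
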