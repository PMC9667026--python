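import numpy as np
import pytest

from ovimorph import geometry, landmarks, synthetic


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.SheepSpec()


@pytest.fixture(scope="session")
def side_bundle(default_spec):
    """Default side-view render: (mask, meta, contour, detected landmarks)."""
    mask, meta = synthetic.render_side(default_spec)
    contour = geometry.extract_contour(mask)
    lset = landmarks.detect_side(contour)
    return mask, meta, contour, lset


@pytest.fixture(scope="session")
def dorsal_bundle(default_spec):
    mask, meta = synthetic.render_dorsal(default_spec)
    contour = geometry.extract_contour(mask)
    lset = landmarks.detect_dorsal(contour)
    return mask, meta, contour, lset


@pytest.fixture(scope="session")
def sim_table():
    """A full simulated survey (332 animals, both sexes)."""
    return synthetic.generate_trait_table(synthetic.SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
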