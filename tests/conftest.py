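import numpy as np
import pytest

from specimenseg.phantom import PhantomSpec, generate_phantom
from specimenseg.pipeline import SegmentationConfig, segment_nodes


@pytest.fixture(scope="session")
def default_phantom():
    """The default easy phantom (3 well-separated high-contrast nodes, seed 0)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    """Segmentation of the default phantom with default config, with stage masks."""
    ct, _, _, _ = default_phantom
    return segment_nodes(ct, SegmentationConfig(), record_masks=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230921)
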