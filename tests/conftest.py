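import numpy as np
import pytest

from ifhdr import hdrmerge, response, synth


@pytest.fixture(scope="session")
def phantom():
    """Default 512x512 phantom, seed 1."""
    return synth.make_phantom(seed=1)


@pytest.fixture(scope="session")
def stack(phantom):
    """Default three-exposure rendering of the phantom (read noise sd 2)."""
    return synth.render_exposures(phantom, seed=1)


@pytest.fixture(scope="session")
def nuclei_mask(stack):
    return response.segment_nuclei(stack.nuclei_images()[0])


@pytest.fixture(scope="session")
def samples(stack, nuclei_mask):
    return response.select_samples(stack, nuclei_mask, seed=1)


@pytest.fixture(scope="session")
def augmented(stack):
    return hdrmerge.make_virtual_exposures(stack)


@pytest.fixture(scope="session")
def curve(augmented, samples):
    return response.fit_response(augmented, samples)


@pytest.fixture(scope="session")
def radiance(augmented, curve):
    return hdrmerge.merge_radiance(augmented, curve)


@pytest.fixture(scope="session")
def small_phantom():
    """128x128 phantom for fast pipeline-level tests."""
    return synth.make_phantom(rows=128, cols=128, n_nuclei=8, seed=7)


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    return synth.render_exposures(small_phantom, seed=7)


@pytest.fixture(scope="session")
def unclipped_somewhere(stack):
    """Pixels with an unclipped value in at least one original exposure."""
    mask = np.zeros(stack.shape, dtype=bool)
    for im in stack.pdl1_images(virtual=False):
        mask |= (im.pixels > 0) & (im.pixels < 4095)
    return mask
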