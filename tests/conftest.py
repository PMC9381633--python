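import numpy as np
import pytest

from synquant import imaging, synthetic


@pytest.fixture(scope="session")
def default_field():
    """One synthetic culture field with ground truth (session-cached)."""
    params = synthetic.ImagingSimParams(seed=7, n_neurites=5)
    fov, truth = synthetic.gen_neuron_field(params)
    return params, fov, truth


@pytest.fixture(scope="session")
def analysed_field(default_field):
    """The default field pushed through the full culture pipeline."""
    params, fov, truth = default_field
    nm = imaging.neurite_mask(fov.channels["MAP2"], fov.pixel_size, scale_um=0.5)
    pre = imaging.detect_puncta(fov.channels["pre"], fov.pixel_size, threshold_spec="otsu")
    post = imaging.detect_puncta(fov.channels["post"], fov.pixel_size, threshold_spec="otsu")
    post_on = imaging.filter_on_neurites(post, nm)
    table = imaging.tally_synapses(pre, post_on)
    return params, fov, truth, nm, pre, post_on, table


def gaussian_spot(shape, cy, cx, height, sigma):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return height * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
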