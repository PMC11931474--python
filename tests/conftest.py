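import numpy as np
import pytest

from syncoloc import ChannelImage, Punctum, PunctaSet, SynthConfig
from syncoloc.synthetic import generate_synapse_field, render_field


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale field: 256 px at 27 nm (~6.9 μm square), noiseless."""
    return SynthConfig(fov_shape=(256, 256), noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_field(small_config):
    gt = generate_synapse_field(small_config)
    images = render_field(gt)
    return gt, images


def make_puncta_set(masks, maxima_px, pixel_size_nm=27.0, shape=(32, 32),
                    label="ch"):
    """Hand-build a PunctaSet from pixel masks and maxima positions."""
    puncta = []
    area = (pixel_size_nm / 1000.0) ** 2
    for i, (mask, (r, c)) in enumerate(zip(masks, maxima_px), start=1):
        coords = np.asarray(sorted(mask), dtype=int)
        puncta.append(Punctum(
            id=i, mask=coords, area_um2=coords.shape[0] * area,
            max_pos_nm=(c * pixel_size_nm, r * pixel_size_nm),
            peak_intensity=1.0))
    return PunctaSet(label, puncta, None, shape, pixel_size_nm)
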