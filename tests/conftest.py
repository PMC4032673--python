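import numpy as np
import pytest
from skimage import draw

from palmgeo import HandParams, render_hand


def rectangle_mask(height, width, angle_deg=0.0, canvas=400):
    """Boolean mask of a height x width rectangle rotated about the canvas
    center (drawn analytically via polygon fill, no interpolation)."""
    if angle_deg == 0.0:  # exact raster extents for the identity case
        mask = np.zeros((canvas, canvas), dtype=bool)
        r0, c0 = canvas // 2 - height // 2, canvas // 2 - width // 2
        mask[r0: r0 + height, c0: c0 + width] = True
        return mask
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    half = np.array([
        [-height / 2, -width / 2], [-height / 2, width / 2],
        [height / 2, width / 2], [height / 2, -width / 2],
    ])
    corners = half @ rot.T + canvas / 2
    rr, cc = draw.polygon(corners[:, 0], corners[:, 1], (canvas, canvas))
    mask = np.zeros((canvas, canvas), dtype=bool)
    mask[rr, cc] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_hand():
    """A noiseless, unrotated synthetic hand image with its ground truth."""
    params = HandParams(noise_sd=0.0)
    return render_hand(params, seed=0)
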