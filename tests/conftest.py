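from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage.measure import label as cc_label

from discmorph.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_phantom(
    seed: int = 0,
    *,
    shape: str = "oval",
    indent: float = 0.0,
    ratio: float = 0.40,
    noise: float = 0.02,
    blur: float = 1.0,
    offset=(0.0, 0.0),
    size=(96, 128),
    axes=(42.0, 30.0),
):
    spec = PhantomSpec(
        image_height_px=size[0],
        image_width_px=size[1],
        disc_semi_axes_px=axes,
        shape_template=shape,
        kidney_indent_depth=indent,
        np_target_ratio=ratio,
        np_center_offset_px=offset,
        noise_sd=noise,
        blur_sigma_px=blur,
        rng_seed=seed,
    )
    return generate_phantom(spec)


@pytest.fixture
def noiseless_phantom():
    """Sharp, noise-free phantom: exactly two intensity values in the disc."""
    return make_phantom(seed=1, noise=0.0, blur=0.0)


@pytest.fixture
def noisy_phantom():
    """Default study-condition phantom: blur 1 px, noise sd 0.02."""
    return make_phantom(seed=2)


def random_blob(rng, shape=(40, 40), quantile=0.8, smooth=3.0):
    """A random single-component, hole-free binary blob."""
    while True:
        img = gaussian_filter(rng.random(shape), smooth)
        mask = img > np.quantile(img, quantile)
        lab = cc_label(mask, connectivity=1)
        if lab.max() == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        blob = binary_fill_holes(lab == (int(np.argmax(sizes)) + 1))
        if blob.sum() >= 20:
            return blob
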