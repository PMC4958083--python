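"""Shared fixtures: analytic slice phantoms and the 3D CT/PET study phantom.

Everything is generated programmatically; the heavier 3D delineation runs
are session-scoped so the contour/voi/acceptance tests share one result.
"""

import numpy as np
import pytest

from marrowdose import (
    ContourParams,
    ImageVolume,
    PhantomSpec,
    delineate,
    generate_ct,
    generate_pet_series,
    rebin_trilinear,
)
from marrowdose.phantom import PET_SPACING, pet_truth_masks


@pytest.fixture(scope="session")
def disk_slice():
    """Noise-free 2D slice: 24 mm-radius disk at 300 HU on 40 HU, 4 mm grid."""
    n, sp = 30, 4.0
    x = np.arange(n) * sp
    cx = n * sp / 2
    xx, yy = np.meshgrid(x, x, indexing="ij")
    disk = (xx - cx) ** 2 + (yy - cx) ** 2 <= 24.0**2
    img = np.where(disk, 300.0, 40.0)
    init = np.zeros_like(disk)
    xs, ys = np.nonzero(disk)
    init[xs.min() - 3 : xs.max() + 4, ys.min() - 3 : ys.max() + 4] = True
    return img, init, disk, sp


def _run_phantom(noise_hu: float, seed: int):
    spec = PhantomSpec(ct_noise_hu=noise_hu, pet_noise_frac=0.0, psf_fwhm_mm=0.0, seed=seed)
    ct, truth = generate_ct(spec)
    pets = generate_pet_series(spec, truth)
    rebinned = rebin_trilinear(ct, PET_SPACING, target_shape=pets[0].shape)
    result = delineate(rebinned, spec.lv_box_mm())
    return spec, pets, result, pet_truth_masks(spec)


@pytest.fixture(scope="session")
def clean_phantom_run():
    """Noise-free, blur-free phantom taken through the full delineation."""
    return _run_phantom(noise_hu=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_phantom_run():
    """Same phantom with 20 HU CT noise (seed 1)."""
    return _run_phantom(noise_hu=20.0, seed=1)
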