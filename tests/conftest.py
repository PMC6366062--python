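import numpy as np
import pytest
from hypothesis import settings

import csaphantom as cp
from csaphantom.phantom_geometry import HoleSpec, PhantomLayout

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    """The standard 110-hole drilling layout, seed 1."""
    return cp.build_layout(seed=1, min_spacing_mm=6.0, margin_mm=4.0)


@pytest.fixture(scope="session")
def noiseless_ct_stack(layout):
    """Noiseless thin-section CT stack: 20 identical sections, no noise."""
    proto = cp.CTProtocol(noise_sd_ref_hu=0.0)
    return cp.simulate_ct_stack(layout, proto, seed=1)


@pytest.fixture(scope="session")
def noiseless_ct_table(layout, noiseless_ct_stack):
    return cp.segment_stack(noiseless_ct_stack, layout, protocol_id="ct_noiseless")


@pytest.fixture(scope="session")
def noisy_ct_stack(layout):
    """The optimized CT condition: 6% iodine, 20 mGy, 100 kVp, 90% strength."""
    return cp.simulate_ct_stack(layout, cp.CTProtocol(n_sections=8), seed=11)


@pytest.fixture(scope="session")
def noisy_ct_table(layout, noisy_ct_stack):
    return cp.segment_stack(noisy_ct_stack, layout, protocol_id="ct_optimal")


def single_hole_layout(diameter_mm: float = 3.0) -> PhantomLayout:
    """A one-hole pseudo-layout for isolated segmentation tests (bypasses the
    110-hole validation, which only applies to built layouts)."""
    return PhantomLayout(
        holes=(HoleSpec(diameter_mm, (0.0, 0.0), 1),),
        min_spacing_mm=6.0,
        seed=0,
        block_diameter_mm=20.0,
    )


def single_disk_image(
    diameter_mm=3.0, pixel_mm=0.39, psf_fwhm_mm=0.6, fov_mm=16.0, supersample=8
):
    """Noiseless blurred disk image and the center pixel coordinates."""
    from scipy import ndimage

    lay = single_hole_layout(diameter_mm)
    cov = cp.rasterize_layout(lay, pixel_mm, supersample, field_of_view_mm=fov_mm)
    if psf_fwhm_mm > 0:
        sigma = psf_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / pixel_mm
        cov = ndimage.gaussian_filter(cov, sigma, mode="constant")
    center = ((cov.shape[0] - 1) / 2.0, (cov.shape[1] - 1) / 2.0)
    return cov, center
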