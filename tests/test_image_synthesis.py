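import math

import numpy as np
import pytest

import csaphantom as cp
from csaphantom.image_synthesis import (
    DELTA_HU,
    CTProtocol,
    MRProtocol,
    MotionState,
    find_background_roi,
    load_stack,
    motion_density_kernel,
    rasterize_layout,
    save_stack,
    simulate_ct_stack,
    simulate_mr_cine,
)
from conftest import single_hole_layout


class TestRasterize:
    def test_single_hole_area(self):
        """Integrated coverage equals the analytic circle area within 0.5%."""
        lay = single_hole_layout(3.0)
        cov = rasterize_layout(lay, 0.39, supersample=16, field_of_view_mm=16.0)
        assert cov.sum() * 0.39**2 == pytest.approx(math.pi * 1.5**2, rel=0.005)
        assert cov.max() <= 1.0 and cov.min() == 0.0

    def test_empty_layout_all_zero(self):
        lay = single_hole_layout(3.0)
        empty = type(lay)(
            holes=(), min_spacing_mm=6.0, seed=0, block_diameter_mm=20.0
        )
        assert not rasterize_layout(empty, 0.39, field_of_view_mm=16.0).any()

    def test_supersample_convergence(self):
        lay = single_hole_layout(3.0)
        a = rasterize_layout(lay, 0.39, supersample=16, field_of_view_mm=16.0)
        b = rasterize_layout(lay, 0.39, supersample=32, field_of_view_mm=16.0)
        # a boundary pixel's count can be off by a few subcell rows: O(1/s)
        # in the worst pixel, far below 1/s^2 on average
        assert np.max(np.abs(a - b)) <= 4.0 / 16**2
        assert np.abs(a - b).mean() <= 0.1 / 16**2
        assert a.sum() == pytest.approx(b.sum(), rel=1e-3)

    def test_supersample_floor(self):
        with pytest.raises(ValueError):
            rasterize_layout(single_hole_layout(), 0.39, supersample=2)


class TestCTProtocol:
    def test_contrast_table(self):
        assert CTProtocol(iodine_pct=6, kvp=100).delta_hu == 560.0
        assert CTProtocol(iodine_pct=3, kvp=120).delta_hu == 170.0

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            CTProtocol(iodine_pct=7, kvp=100).validate()

    def test_noise_monotone_in_dose_and_strength(self):
        """Noise SD strictly decreases with dose and reconstruction strength."""
        sd = lambda **kw: CTProtocol(**kw).noise_sd_hu
        assert sd(ctdi_mgy=5) > sd(ctdi_mgy=10) > sd(ctdi_mgy=20)
        assert sd(asirv_pct=0) > sd(asirv_pct=50) > sd(asirv_pct=90)


class TestSimulateCT:
    def test_noiseless_lumen_center_value(self, layout):
        """Deep inside a hole the pixel reads background + contrast HU."""
        proto = CTProtocol(
            iodine_pct=6, kvp=100, noise_sd_ref_hu=0.0, psf_fwhm_mm=0.0, n_sections=1
        )
        stack = simulate_ct_stack(layout, proto, seed=0)
        assert stack.pixels.max() == pytest.approx(proto.background_hu + 560.0, abs=0.01)
        r0, c0, nr, nc = stack.background_roi
        assert np.allclose(stack.pixels[0, r0:r0+nr, c0:c0+nc], proto.background_hu)

    def test_seed_determinism(self, layout):
        a = simulate_ct_stack(layout, CTProtocol(n_sections=2), seed=7)
        b = simulate_ct_stack(layout, CTProtocol(n_sections=2), seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_background_sd_follows_sqrt_dose(self, layout):
        """Background SD ratio between 20 and 5 mGy is 1/2 within 5%."""
        p20 = CTProtocol(ctdi_mgy=20, asirv_pct=0, n_sections=12)
        p5 = CTProtocol(ctdi_mgy=5, asirv_pct=0, n_sections=12)
        s20 = simulate_ct_stack(layout, p20, seed=3)
        s5 = simulate_ct_stack(layout, p5, seed=4)
        assert s20.background_pixels().size >= 10_000
        ratio = np.std(s20.background_pixels()) / np.std(s5.background_pixels())
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_thick_sections_average_noise(self, layout):
        """5-mm sections: noise SD reduced by sqrt(8) vs 0.625-mm sections."""
        thin = CTProtocol(asirv_pct=0, n_sections=16)
        thick = CTProtocol(asirv_pct=0, n_sections=16, section_mm=5.0)
        a = simulate_ct_stack(layout, thin, seed=5)
        b = simulate_ct_stack(layout, thick, seed=5)
        ratio = np.std(b.background_pixels()) / np.std(a.background_pixels())
        assert ratio == pytest.approx(1 / math.sqrt(8), rel=0.06)

    def test_contrast_monotone_in_iodine(self, layout):
        """Lumen-minus-background contrast increases with iodine at fixed kVp."""
        peaks = []
        for io in (3, 4, 5, 6):
            p = CTProtocol(iodine_pct=io, noise_sd_ref_hu=0.0, n_sections=1)
            st = simulate_ct_stack(layout, p, seed=0)
            peaks.append(st.pixels.max() - p.background_hu)
        assert all(b > a for a, b in zip(peaks, peaks[1:]))
        expected = [DELTA_HU[(io, 100)] for io in (3, 4, 5, 6)]
        assert peaks == pytest.approx(expected, abs=0.01)

    def test_motion_conserves_total_signal(self, layout):
        """Blur by a unit-mass kernel preserves integrated excess intensity."""
        p = CTProtocol(noise_sd_ref_hu=0.0, n_sections=1)
        static = simulate_ct_stack(layout, p, seed=0)
        moving = simulate_ct_stack(layout, p, motion=MotionState(), seed=0)
        e0 = np.sum(static.pixels[0] - p.background_hu)
        e1 = np.sum(moving.pixels[0] - p.background_hu)
        assert e1 == pytest.approx(e0, rel=0.005)


class TestSimulateMR:
    def test_noiseless_lumen_equals_target_snr(self, layout):
        proto = MRProtocol(gd_mmol_l=0.67, psf_fwhm_mm=0.0, n_frames=1)
        stack = simulate_mr_cine(layout, proto, seed=0, noise_sd=0.0)
        assert stack.pixels.max() == pytest.approx(proto.target_snr, abs=1e-6)

    def test_measured_snr_matches_map(self, layout):
        """Round trip: simulated stack measures back its target SNR within 10%."""
        proto = MRProtocol(gd_mmol_l=1.66, n_frames=10)
        stack = simulate_mr_cine(layout, proto, seed=9)
        _, summary = cp.snr(stack)
        assert summary.mean == pytest.approx(73.5, rel=0.10)

    def test_zero_amplitude_motion_is_static(self, layout):
        proto = MRProtocol(n_frames=2)
        a = simulate_mr_cine(layout, proto, seed=4)
        b = simulate_mr_cine(
            layout, proto, motion=MotionState(amplitude_mm=0.0), seed=4
        )
        assert np.array_equal(a.pixels, b.pixels)

    def test_unknown_concentration_rejected(self, layout):
        with pytest.raises(ValueError):
            simulate_mr_cine(layout, MRProtocol(gd_mmol_l=0.42), seed=0)

    def test_snr_map_must_be_monotone(self):
        with pytest.raises(ValueError):
            MRProtocol(target_snr_by_conc=((0.0, 30.0), (1.0, 20.0))).validate()


class TestMotionKernel:
    def test_zero_window_is_delta(self):
        k = motion_density_kernel(MotionState(), 0.0, 0.39)
        assert k.tolist() == [1.0]

    def test_normalization(self):
        k = motion_density_kernel(MotionState(), 0.14, 0.39)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "window,pixel", [(0.14, 0.39), (0.095, 0.39), (0.14, 0.625), (0.095, 0.625)]
    )
    def test_support_matches_analytic_displacement(self, window, pixel):
        """Kernel support span agrees with the closed-form displacement
        within one pixel, for the CT and MR protocol windows."""
        m = MotionState()
        k = motion_density_kernel(m, window, pixel)
        nz = np.nonzero(k)[0]
        span_mm = (nz[-1] - nz[0]) * pixel
        dx = cp.window_displacement(m, cp.AcquisitionWindow(window))
        assert abs(span_mm - dx) <= pixel + 1e-9

    def test_window_longer_than_period_rejected(self):
        with pytest.raises(ValueError):
            motion_density_kernel(MotionState(), 1.5, 0.39)


class TestStackIO:
    @pytest.mark.parametrize("ext", ["tiff", "nii"])
    def test_round_trip(self, layout, tmp_path, ext):
        stack = simulate_ct_stack(layout, CTProtocol(n_sections=2), seed=1)
        lp = tmp_path / "layout.csv"
        layout.to_csv(lp)
        p = tmp_path / f"stack.{ext}"
        save_stack(stack, p, layout_path=lp)
        back = load_stack(p)
        assert np.allclose(back.pixels, stack.pixels, atol=1e-4)
        assert back.pixel_mm == stack.pixel_mm
        assert back.modality == "CT"
        assert back.background_roi == stack.background_roi
        assert back.protocol == stack.protocol


def test_background_roi_clear_of_holes(layout):
    shape = (283, 283)
    r0, c0, nr, nc = find_background_roi(layout, 0.39, shape, psf_fwhm_mm=0.6)
    cov = rasterize_layout(layout, 0.39, field_of_view_mm=283 * 0.39)
    assert nr * nc >= 100
    assert not cov[r0 : r0 + nr, c0 : c0 + nc].any()
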