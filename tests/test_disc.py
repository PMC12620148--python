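"""Shift map, unwarping, Z-spectrum correction, and the DISC pipeline."""

import numpy as np
import pytest

import cestdisc as cd
from cestdisc.b0map import FieldMap
from cestdisc.disc import (
    ShiftMap,
    compute_shift_map,
    correct_zspectrum,
    run_disc,
    unwarp_frame,
)
from cestdisc.protocol import ReadoutParams, mouse_schedule
from cestdisc.simulate import FieldModel, LorentzianPool, forward_distort, synth_zspectrum


def _epi(n=96, esp=5e-4, pol=+1):
    return ReadoutParams("EPI", tr_s=6.0, n_pe=n, n_fe=n, esp_s=esp,
                         pe_polarity=pol, f0_mhz=127.7)


def _const_field(shape, ppm, f0=127.7):
    return FieldMap(np.full(shape, ppm), np.ones(shape, bool), f0)


class TestShiftMap:
    def test_fifty_hz_gives_2p4_px(self):
        # Δf=50 Hz, Npe=96, ESP=0.5 ms → 50·96·0.0005 = 2.4 px
        fm = _const_field((4, 4), 50.0 / 127.7)
        sm = compute_shift_map(fm, _epi())
        assert sm.shift_px[0, 0] == pytest.approx(2.4, rel=1e-9)

    def test_zero_field_zero_shift(self):
        sm = compute_shift_map(_const_field((4, 4), 0.0), _epi())
        assert np.all(sm.shift_px == 0)

    @pytest.mark.parametrize("factor", [2.0, 0.5])
    def test_linearity_in_esp_npe_field(self, factor):
        fm = _const_field((4, 4), 0.1)
        base = compute_shift_map(fm, _epi()).shift_px[0, 0]
        assert compute_shift_map(fm, _epi(esp=5e-4 * factor)).shift_px[0, 0] == pytest.approx(base * factor)
        assert compute_shift_map(_const_field((4, 4), 0.1 * factor), _epi()).shift_px[0, 0] == pytest.approx(base * factor)

    def test_polarity_flips_sign(self):
        fm = _const_field((4, 4), 0.1)
        up = compute_shift_map(fm, _epi(pol=+1)).shift_px
        down = compute_shift_map(fm, _epi(pol=-1)).shift_px
        np.testing.assert_allclose(up, -down)

    def test_missing_esp_rejected(self):
        with pytest.raises(ValueError, match="esp"):
            compute_shift_map(_const_field((4, 4), 0.1),
                              ReadoutParams("EPI", tr_s=6.0))

    def test_invalid_field_pixels_get_zero_shift(self):
        fm = FieldMap(np.full((4, 4), 0.3), np.zeros((4, 4), bool), 127.7)
        sm = compute_shift_map(fm, _epi())
        assert np.all(sm.shift_px == 0) and not sm.valid_mask.any()


class TestUnwarp:
    def test_zero_shift_identity(self, rng):
        img = rng.random((16, 16))
        sm = ShiftMap(np.zeros((16, 16)), np.ones((16, 16), bool))
        np.testing.assert_array_equal(unwarp_frame(img, sm), img)

    def test_constant_integer_shift_translates_back(self, rng):
        img = rng.random((8, 20))
        sm = ShiftMap(np.full((8, 20), 2.0), np.ones((8, 20), bool))
        out = unwarp_frame(img, sm)
        np.testing.assert_allclose(out[:, :-2], img[:, 2:], atol=1e-12)

    def test_distort_unwarp_round_trip_on_smooth_image(self):
        """Constant sub-pixel shift round trip: exact on profiles the
        linear interpolant reproduces, so any residual is coordinate
        bookkeeping error."""
        nx = ny = 32
        x = np.arange(nx)[:, None]
        y = np.arange(ny)[None, :]
        img = 1.0 + 0.01 * y + 0.3 * np.sin(2 * np.pi * x / nx) * (1 + 0.02 * y)
        shift = np.full((nx, ny), 0.37)
        distorted = forward_distort(img, shift)
        sm = ShiftMap(shift, np.ones((nx, ny), bool))
        out = unwarp_frame(distorted, sm)
        interior = (slice(None), slice(2, -2))
        assert np.max(np.abs(out[interior] - img[interior])) <= 1e-6

    def test_nonfinite_shift_at_valid_pixel_rejected(self):
        bad = np.zeros((4, 4))
        bad[1, 1] = np.inf
        with pytest.raises(ValueError):
            ShiftMap(bad, np.ones((4, 4), bool))

    def test_pileup_not_invertible(self):
        """Strongly converging shifts accumulate intensity that pull-back
        resampling cannot redistribute — the documented method boundary."""
        nx = ny = 48
        rng = np.random.default_rng(0)
        img = np.ones((nx, ny)) + 0.2 * np.sin(np.arange(ny) / 3.0)[None, :]
        # shifts converging onto y=24 with slope < -1 (fold-over regime)
        ys = np.arange(ny, dtype=float)[None, :]
        shift = np.clip(1.5 * (24.0 - ys), -8, 8) * np.ones((nx, 1))
        distorted = forward_distort(img, shift)
        sm = ShiftMap(shift, np.ones((nx, ny), bool))
        out = unwarp_frame(distorted, sm)
        interior = (slice(None), slice(8, -8))
        assert np.max(np.abs(out[interior] - img[interior])) > 0.05


class TestZSpectrumCorrection:
    offsets = np.array(mouse_schedule().offsets_ppm)

    def test_zero_shift_identity(self):
        z = synth_zspectrum([LorentzianPool(0.8, 2.0, 0.0)], self.offsets)
        np.testing.assert_array_equal(correct_zspectrum(z, self.offsets, 0.0), z)

    def test_correction_recentres_minimum(self):
        z = synth_zspectrum([LorentzianPool(0.8, 2.0, 0.0)], self.offsets, 0.3)
        zc = correct_zspectrum(z, self.offsets, 0.3)
        grid = np.linspace(-1, 1, 2001)
        from scipy.interpolate import CubicSpline

        dense = CubicSpline(self.offsets, zc)(grid)
        assert grid[np.argmin(dense)] == pytest.approx(0.0, abs=1e-3)

    def test_pure_ds_asymmetry_nulled_after_correction(self):
        z = synth_zspectrum([LorentzianPool(0.9, 1.5, 0.0)], self.offsets, 0.3)
        zs_before = cd.ZSpectrum(self.offsets, z)
        assert abs(cd.mtr_asym(zs_before, 2.0)) > 1e-2
        zc = correct_zspectrum(z, self.offsets, 0.3)
        assert abs(cd.mtr_asym(cd.ZSpectrum(self.offsets, zc), 2.0)) <= 1e-3

    def test_range_preserved(self):
        z = synth_zspectrum([LorentzianPool(0.9, 0.8, 0.0)], self.offsets, 0.4)
        zc = correct_zspectrum(z, self.offsets, 0.4)
        assert zc.min() >= z.min() - 1e-12 and zc.max() <= z.max() + 1e-12

    def test_nonfinite_b0_propagates_invalid(self):
        z = np.ones_like(self.offsets)
        out = correct_zspectrum(z, self.offsets, np.nan)
        assert np.all(np.isnan(out))

    def test_extrapolated_points_flagged(self):
        z = synth_zspectrum([LorentzianPool(0.8, 2.0, 0.0)], self.offsets)
        _, flags = correct_zspectrum(z, self.offsets, 0.5, return_flags=True)
        assert flags[-1] and not flags[0]


class TestRunDisc:
    def test_zero_field_near_identity(self):
        spec = cd.make_creatine_phantom(grid=(32, 32), seed=0, snr=np.inf,
                                        field_model=FieldModel())
        epi, _, gt = cd.simulate_dataset(spec)
        res = run_disc(epi)
        # a one-grid-step (0.001 ppm) estimate maps to ~2e-3 px of shift,
        # hence intensity changes of the same order at steep edges
        np.testing.assert_allclose(res.unwarped_raw.data, epi.data, atol=5e-3)
        assert np.abs(res.field_initial.delta_b0_ppm).max() <= 2e-3
        assert np.abs(res.field_disc.delta_b0_ppm).max() <= 2e-3

    def test_correction_improves_ssim_and_field(self, creatine_snr40):
        _, epi, _, gt = creatine_snr40
        res = run_disc(epi)
        _, before = cd.dataset_ssim(epi, gt.clean_stack)
        _, after = cd.dataset_ssim(res.unwarped_raw, gt.clean_stack)
        assert after > before
        obj = gt.label_map >= 0
        rmse_disc = res.field_disc.rmse_vs(gt.field.delta_b0_ppm, obj)
        rmse_init = res.field_initial.rmse_vs(gt.field.delta_b0_ppm, obj)
        # the DISC field is estimated in corrected geometry, so it should
        # track the true (undistorted-frame) field at least as well
        assert rmse_disc <= rmse_init * 1.5

    def test_normalized_input_rejected(self, creatine_noiseless):
        _, epi, _, _ = creatine_noiseless
        with pytest.raises(ValueError):
            run_disc(cd.normalize_stack(epi))

    def test_intermediates_returned(self, creatine_noiseless):
        _, epi, _, _ = creatine_noiseless
        res = run_disc(epi)
        assert res.corrected.normalized
        assert res.corrected.data.shape[2] == epi.schedule.n_offsets
        assert res.shift_map.shift_px.shape == epi.data.shape[:2]
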