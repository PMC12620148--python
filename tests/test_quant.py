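"""Normalization, MTRasym, DS reference fit, inverse-Z contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cestdisc as cd
from cestdisc.disc import CestStack
from cestdisc.protocol import build_schedule, mouse_schedule
from cestdisc.quant import (
    DS_FIT_RANGES_PPM,
    ZSpectrum,
    cest_rex,
    fit_ds_lorentzian,
    mtr_asym,
    mtr_asym_map,
    normalize_stack,
)
from cestdisc.simulate import LorentzianPool, synth_zspectrum


def _raw_stack(m0_values, sat_value, schedule):
    data = np.empty((1, 1, schedule.n_frames))
    data[0, 0, schedule.m0_frame_indices] = m0_values
    data[0, 0, schedule.offset_frame_indices] = sat_value
    return CestStack(data=data, schedule=schedule)


class TestNormalize:
    sched = build_schedule([(-2, 2, 1.0)], n_m0=3)

    def test_msat_equals_m0_gives_unit_z(self):
        stack = _raw_stack([7.0, 7.0, 7.0], 7.0, self.sched)
        z = normalize_stack(stack)
        assert np.all(z.data == 1.0)

    def test_last_two_m0_frames_averaged(self):
        # M0 frames (10, 8, 12): denominator = mean(8, 12) = 10
        stack = _raw_stack([10.0, 8.0, 12.0], 5.0, self.sched)
        z = normalize_stack(stack)
        assert np.all(z.data == pytest.approx(0.5))

    def test_zero_m0_voxel_flagged_invalid(self):
        stack = _raw_stack([0.0, 0.0, 0.0], 5.0, self.sched)
        z = normalize_stack(stack)
        assert not z.valid_mask[0, 0]
        assert np.all(z.data == 0)

    def test_single_m0_warns_and_uses_it(self):
        sched = build_schedule([(-2, 2, 1.0)], n_m0=1)
        stack = _raw_stack([4.0], 2.0, sched)
        with pytest.warns(UserWarning):
            z = normalize_stack(stack)
        assert np.all(z.data == pytest.approx(0.5))

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, c):
        """Multiplying raw frames by c > 0 leaves Z unchanged."""
        base = _raw_stack([10.0, 8.0, 12.0], 5.0, self.sched)
        scaled = CestStack(data=base.data * c, schedule=self.sched)
        np.testing.assert_allclose(
            normalize_stack(scaled).data, normalize_stack(base).data, rtol=1e-12
        )


class TestMtrAsym:
    offsets = np.array(mouse_schedule().offsets_ppm)

    def test_symmetric_spectrum_zero(self):
        z = synth_zspectrum([LorentzianPool(0.8, 2.0, 0.0)], self.offsets)
        assert mtr_asym(ZSpectrum(self.offsets, z), 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_plain_arithmetic(self):
        offs = np.array([-2.0, 0.0, 2.0])
        zs = ZSpectrum(offs, np.array([0.9, 0.1, 0.8]))
        assert mtr_asym(zs, 2.0) == pytest.approx(0.1)

    def test_probe_outside_range_rejected(self):
        offs = np.array([-1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            mtr_asym(ZSpectrum(offs, np.ones(3)), 2.0)

    def test_antisymmetric_in_probe(self):
        pools = [LorentzianPool(0.8, 2.0, 0.0), LorentzianPool(0.1, 1.0, 2.0)]
        zs = ZSpectrum(self.offsets, synth_zspectrum(pools, self.offsets))
        assert mtr_asym(zs, 2.0) == pytest.approx(-mtr_asym(zs, -2.0))

    def test_creatine_disks_monotone_in_concentration(self):
        """Noiseless, zero-field MTRasym(2 ppm) ranks the six tubes by
        concentration (with a B0 shift the asymmetry is confounded until
        Z-spectrum correction — that artifact is tested elsewhere)."""
        from cestdisc.simulate import FieldModel

        spec = cd.make_creatine_phantom(grid=(48, 48), seed=0, snr=np.inf,
                                        field_model=FieldModel())
        _, rare, gt = cd.simulate_dataset(spec)
        norm = normalize_stack(rare)
        cm = mtr_asym_map(norm, 2.0)
        labels = list(gt.region_labels)
        means = [
            float(cm.values[gt.label_map == labels.index(f"cr{c}mM")].mean())
            for c in (5, 10, 20, 30, 40, 50)
        ]
        assert all(b > a for a, b in zip(means, means[1:]))
        water = float(cm.values[gt.label_map == labels.index("water")].mean())
        assert abs(water) < 1e-6


class TestDsFit:
    offsets = np.array(mouse_schedule().offsets_ppm)

    def test_parameter_recovery_noiseless(self):
        truth = dict(a=0.85, g=1.8, d=0.05, b=1.0)
        z = truth["b"] - truth["a"] * (truth["g"] ** 2 / 4) / (
            truth["g"] ** 2 / 4 + (self.offsets - truth["d"]) ** 2
        )
        fit = fit_ds_lorentzian(ZSpectrum(self.offsets, z))
        assert fit.amplitude == pytest.approx(truth["a"], rel=1e-4)
        assert fit.width_ppm == pytest.approx(truth["g"], rel=1e-4)
        assert fit.center_ppm == pytest.approx(truth["d"], abs=1e-4)
        assert fit.baseline == pytest.approx(truth["b"], rel=1e-4)

    def test_flat_spectrum_zero_amplitude(self):
        fit = fit_ds_lorentzian(ZSpectrum(self.offsets, np.ones_like(self.offsets)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-4)
        assert np.allclose(fit.z_ref(self.offsets), 1.0, atol=1e-4)

    def test_amide_outside_fit_ranges_barely_biases(self):
        ds = LorentzianPool(0.85, 1.4, 0.0)
        amide = LorentzianPool(0.05, 1.5, 3.5)
        z_clean = synth_zspectrum([ds], self.offsets)
        z_cont = synth_zspectrum([ds, amide], self.offsets)
        f0 = fit_ds_lorentzian(ZSpectrum(self.offsets, z_clean))
        f1 = fit_ds_lorentzian(ZSpectrum(self.offsets, z_cont))
        assert f1.amplitude == pytest.approx(f0.amplitude, rel=0.01)
        assert f1.width_ppm == pytest.approx(f0.width_ppm, rel=0.01)

    def test_too_few_points_rejected(self):
        offs = np.array([-0.5, 0.0, 0.5])
        with pytest.raises(ValueError, match=">= 6"):
            fit_ds_lorentzian(ZSpectrum(offs, np.ones(3)))


class TestCestRex:
    def test_equal_z_gives_zero(self):
        assert cest_rex(0.5, 0.5) == 0.0

    def test_plain_arithmetic(self):
        assert cest_rex(0.5, 1.0) == pytest.approx(1.0)

    def test_z_floor_guards_blowup(self):
        assert np.isnan(cest_rex(0.01, 0.9))

    def test_brain_apt_recovery_and_tumor_contrast(self, brain_tumor_noiseless):
        """Map means recover the analytic single-voxel inverse-Z contrast
        and the tumor is hypointense vs contralateral brain."""
        spec, _, rare, gt = brain_tumor_noiseless
        norm = normalize_stack(rare)
        labels = list(gt.region_labels)
        brain_sel = np.isin(gt.label_map, [labels.index("brain"), labels.index("tumor")])
        apt = cd.cest_rex_map(norm, 3.5, mask=brain_sel)
        brain_reg = next(r for r in spec.regions if r.label == "brain")
        offs = np.array(spec.schedule.offsets_ppm)
        z0 = synth_zspectrum(brain_reg.pools, offs)
        ref_fit = fit_ds_lorentzian(ZSpectrum(offs, z0))
        zp = float(np.interp(3.5, offs, z0))
        single_voxel = 1.0 / zp - 1.0 / ref_fit.z_ref(3.5)
        contra = float(np.nanmean(apt.values[(gt.label_map == labels.index("brain")) & apt.mask]))
        tumor = float(np.nanmean(apt.values[(gt.label_map == labels.index("tumor")) & apt.mask]))
        assert contra == pytest.approx(single_voxel, rel=0.15)
        assert tumor < contra

    def test_rex_nonnegative_when_z_below_reference(self, brain_tumor_noiseless):
        spec, _, rare, gt = brain_tumor_noiseless
        norm = normalize_stack(rare)
        labels = list(gt.region_labels)
        sel = gt.label_map == labels.index("brain")
        apt = cd.cest_rex_map(norm, 3.5, mask=sel)
        assert np.all(apt.values[apt.mask] >= -1e-9)
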