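"""NU4 analyses: resolution estimator, sensitivity, count rates, IQ."""

import numpy as np
import pytest
from scipy import ndimage

from annpet.nema import (countrate_metrics, iq_metrics, profile_widths,
                         resolution_metrics, sensitivity_metrics)
from annpet.phantoms import IQPhantomSpec
from annpet.recon import ImageVolume, SinogramSpec


def _gaussian_volume(sigma=0.6, vox=0.25, n=96, amplitude=1.0):
    c = (np.arange(n) + 0.5) * vox - n * vox / 2
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    vals = amplitude * np.exp(-(X**2 + Y**2 + Z**2) / (2 * sigma**2))
    return ImageVolume(vals.astype(np.float32), (vox,) * 3,
                       np.array([c[0] - vox / 2] * 3))


class TestResolution:
    def test_gaussian_fwhm_closed_form(self):
        res = resolution_metrics(_gaussian_volume(), (0, 0, 0))
        for ax in ("radial", "tangential", "axial"):
            assert res[ax]["fwhm"] == pytest.approx(2.3548 * 0.6, rel=0.02)
            assert res[ax]["fwtm"] / res[ax]["fwhm"] == pytest.approx(
                1.8226, rel=0.02)

    def test_intensity_scale_invariance(self):
        r1 = resolution_metrics(_gaussian_volume(amplitude=1.0), (0, 0, 0))
        r2 = resolution_metrics(_gaussian_volume(amplitude=413.0), (0, 0, 0))
        assert r1["radial"]["fwhm"] == pytest.approx(r2["radial"]["fwhm"])

    def test_upsampling_consistency(self):
        """Doubling the voxel count by trilinear upsampling barely moves
        FWHM (the ~1 % residual is the interpolation plateau at the peak)."""
        vol = _gaussian_volume(vox=0.25, n=96)
        r1 = resolution_metrics(vol, (0, 0, 0))
        up = ndimage.zoom(vol.values, 2.0, order=1, grid_mode=True,
                          mode="nearest")
        vol2 = ImageVolume(up, (0.125,) * 3, vol.origin)
        r2 = resolution_metrics(vol2, (0, 0, 0))
        assert r2["radial"]["fwhm"] == pytest.approx(r1["radial"]["fwhm"],
                                                     rel=0.015)

    def test_empty_volume_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8), np.float32), (1.0,) * 3,
                          np.zeros(3))
        with pytest.raises(ValueError, match="peak"):
            resolution_metrics(vol, (0, 0, 0))

    def test_profile_widths_requires_peak(self):
        with pytest.raises(ValueError):
            profile_widths(np.zeros(10), np.arange(10.0))


class TestSensitivity:
    def test_printed_value_conversions(self):
        """Rate -> absolute sensitivity uses the Na-22 branching 0.9060."""
        s = sensitivity_metrics([0.086], 0.0, 1.0, "Na22")
        assert s["peak_absolute_pct"] == pytest.approx(9.49, abs=0.01)
        s15 = sensitivity_metrics(np.full(15, 0.751 / 15), 0.0, 1.0, "Na22")
        assert s15["integrated_cps_per_bq"] == pytest.approx(0.751)
        assert s15["integrated_absolute_pct"] == pytest.approx(82.9, abs=0.05)

    def test_zero_counts_zero_sensitivity(self):
        s = sensitivity_metrics([0.0, 0.0], 0.0, 1e6)
        assert s["peak_cps_per_bq"] == 0.0

    def test_background_subtraction(self):
        s = sensitivity_metrics([10.0], 10.0, 1e3)
        assert s["peak_cps_per_bq"] == 0.0

    def test_invalid_activity(self):
        with pytest.raises(ValueError):
            sensitivity_metrics([1.0], 0.0, 0.0)


def _necr_sinogram(spec, trues, scatter):
    n_r, n_a = spec.n_radial, spec.n_angles
    cen = spec.radial_centers()
    sino = np.zeros((n_r, n_a))
    sino[n_r // 2, :] = trues / n_a
    k1, k2 = np.argmin(np.abs(cen - 15)), np.argmin(np.abs(cen + 15))
    sino[k1, :] = scatter / 2 / n_a
    sino[k2, :] = scatter / 2 / n_a
    return sino


class TestCountRates:
    spec = SinogramSpec()

    def test_necr_closed_form(self):
        """T = 9e5, S = 1e5, R = 0 -> NECR = T^2/(T+S) = 8.1e5."""
        sinos = [_necr_sinogram(self.spec, 9e5, 1e5),
                 _necr_sinogram(self.spec, 4.5e5, 5e4)]
        res = countrate_metrics(sinos, [1e6, 5e5], 1.0,
                                r_bin=self.spec.r_bin, r_max=self.spec.r_max)
        r0 = res["acquisitions"][0]
        assert r0["trues_cps"] == pytest.approx(9e5, rel=1e-6)
        assert r0["scatter_cps"] == pytest.approx(1e5, rel=1e-6)
        assert r0["necr_cps"] == pytest.approx(8.1e5, rel=1e-6)
        assert res["scatter_fraction"] == pytest.approx(0.1, rel=1e-6)

    def test_all_zero_sinograms(self):
        z = np.zeros((self.spec.n_radial, self.spec.n_angles))
        res = countrate_metrics([z, z], [2.0, 1.0], 1.0,
                                r_bin=self.spec.r_bin, r_max=self.spec.r_max)
        assert all(r["total_cps"] == 0 for r in res["acquisitions"])

    def test_scatter_outside_strip_fully_recovered(self):
        """Counts placed wholly outside the 14 mm strip come back as S."""
        sino = _necr_sinogram(self.spec, 0.0, 4e4)
        sino[self.spec.n_radial // 2, :] = 1e5 / self.spec.n_angles
        res = countrate_metrics([sino, sino * 0.5], [1e5, 5e4], 1.0,
                                r_bin=self.spec.r_bin, r_max=self.spec.r_max)
        assert res["acquisitions"][0]["scatter_cps"] == pytest.approx(4e4,
                                                                      rel=1e-6)

    def test_randoms_split(self):
        sino = _necr_sinogram(self.spec, 9e5, 1e5)
        res = countrate_metrics([sino, sino], [1e6, 9e5], 1.0,
                                randoms_rates=[3e4, 3e4],
                                r_bin=self.spec.r_bin, r_max=self.spec.r_max)
        r0 = res["acquisitions"][0]
        assert r0["randoms_cps"] == pytest.approx(3e4)
        assert r0["scatter_cps"] == pytest.approx(7e4)
        # NECR = T^2 / total with all components
        assert r0["necr_cps"] == pytest.approx(9e5**2 / 1e6)

    def test_single_acquisition_rejected(self):
        with pytest.raises(ValueError):
            countrate_metrics([np.zeros((10, 4))], [1.0], 1.0,
                              r_bin=1.0, r_max=5.0)

    def test_phantom_outside_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            countrate_metrics([np.zeros((10, 4))] * 2, [2.0, 1.0], 1.0,
                              r_bin=1.0, r_max=5.0)


def _digital_iq(ph, vox=0.5, blur_sigma=0.0):
    nx, nz = 80, 120
    cx = (np.arange(nx) + 0.5) * vox - nx * vox / 2
    cz = (np.arange(nz) + 0.5) * vox - nz * vox / 2
    X, Y, Z = np.meshgrid(cx, cx, cz, indexing="ij")
    act = np.zeros((nx, nx, nz), np.float32)
    zu0, zu1 = ph.uniform_zrange
    act[(X**2 + Y**2 <= 15**2) & (Z >= zu0) & (Z <= zu1)] = 1.0
    zr0, zr1 = ph.rod_zrange
    for d, (rx, ry) in zip(ph.rod_diameters, ph.rod_centers()):
        act[((X - rx) ** 2 + (Y - ry) ** 2 <= (d / 2) ** 2)
            & (Z >= zr0) & (Z <= zr1)] = 1.0
    if blur_sigma > 0:
        act = ndimage.gaussian_filter(act, blur_sigma / vox)
    return ImageVolume(act, (vox,) * 3,
                       np.array([cx[0] - vox / 2, cx[0] - vox / 2,
                                 cz[0] - vox / 2]))


class TestImageQuality:
    ph = IQPhantomSpec()

    def test_ideal_phantom(self):
        iq = iq_metrics(_digital_iq(self.ph), self.ph)
        assert iq["uniformity"]["pct_std"] == pytest.approx(0.0, abs=1e-9)
        for v in iq["recovery_coefficients"].values():
            assert v["rc"] == pytest.approx(1.0)
        assert iq["spillover_ratios"]["water"]["sor"] == 0.0
        assert iq["spillover_ratios"]["air"]["sor"] == 0.0

    def test_rc_monotone_under_blur(self):
        """Partial-volume loss orders RC by rod diameter."""
        iq = iq_metrics(_digital_iq(self.ph, blur_sigma=0.6), self.ph)
        rcs = [iq["recovery_coefficients"][f"{d:.0f}mm"]["rc"]
               for d in (1, 2, 3, 4, 5)]
        assert all(a < b for a, b in zip(rcs, rcs[1:]))
        assert rcs[0] < 0.9

    def test_registration_required(self):
        with pytest.raises(ValueError):
            iq_metrics(_digital_iq(self.ph), None)
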