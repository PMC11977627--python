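"""Parametric light model: linearity, symmetry, containment, noise."""

import numpy as np
import pytest

from annpet.optics import (NoiseConfig, OpticalModel, expected_light_map,
                           make_gain_map, sample_signals, three_facet_fraction)


def _on_axis_point(geom, depth):
    return np.array([[geom.annulus.facet_apothem - depth, 0.0, 0.0]])


class TestExpectedLight:
    def test_linearity_in_energy(self, geom, optical_model):
        p = _on_axis_point(geom, 4.0)
        m1 = expected_light_map(p, [511.0], optical_model, geom)
        m2 = expected_light_map(p, [1022.0], optical_model, geom)
        assert np.allclose(m2, 2 * m1, rtol=1e-6)

    def test_transaxial_symmetry_on_facet_axis(self, geom, optical_model):
        m = expected_light_map(_on_axis_point(geom, 5.0), [511.0],
                               optical_model, geom)
        f0 = m[0, 0]  # (4 transaxial, 16 axial)
        assert np.abs(f0 - f0[::-1, :]).max() <= 1e-6 * f0.max()

    def test_outside_crystal_rejected(self, geom, optical_model):
        with pytest.raises(ValueError, match="outside"):
            expected_light_map(np.array([[0.0, 0.0, 0.0]]), [511.0],
                               optical_model, geom)

    def test_three_facet_containment(self, geom, optical_model,
                                     uniform_pe_points):
        """>= 90 % of expected light within primary facet +/- 1."""
        pts = uniform_pe_points[:1500]
        maps = expected_light_map(pts, np.full(len(pts), 511.0),
                                  optical_model, geom)
        frac = three_facet_fraction(maps)
        assert frac.mean() >= 0.90
        assert np.quantile(frac, 0.05) >= 0.85

    def test_containment_across_depth_sweep(self, geom, optical_model):
        for depth in (0.5, 2.0, 5.0, 9.0):
            m = expected_light_map(_on_axis_point(geom, depth), [511.0],
                                   optical_model, geom)
            assert three_facet_fraction(m)[0] >= 0.90

    def test_zero_reflectance_kills_mirror_term(self, geom):
        m_ref = expected_light_map(_on_axis_point(geom, 4.0), [511.0],
                                   OpticalModel(inner_reflectance=0.95), geom)
        m_off = expected_light_map(_on_axis_point(geom, 4.0), [511.0],
                                   OpticalModel(inner_reflectance=0.0), geom)
        assert m_off.sum() < m_ref.sum()
        # mirror contribution = difference, scales linearly with rho
        m_half = expected_light_map(_on_axis_point(geom, 4.0), [511.0],
                                    OpticalModel(inner_reflectance=0.475), geom)
        assert m_half.sum() == pytest.approx(
            0.5 * (m_ref.sum() + m_off.sum()), rel=1e-6)

    def test_total_signal_monotone_in_attenuation_length(self, geom):
        """Shorter optical attenuation lengths collect strictly less light."""
        p = _on_axis_point(geom, 5.0)
        totals = [expected_light_map(p, [511.0],
                                     OpticalModel(attenuation_length=L),
                                     geom).sum()
                  for L in (400.0, 200.0, 50.0, 20.0)]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_restricted_fast_path_matches_full(self, geom, optical_model):
        p = _on_axis_point(geom, 6.0)
        full = expected_light_map(p, [511.0], optical_model, geom)
        fast = expected_light_map(p, [511.0], optical_model, geom, facets=[0])
        ref = np.stack([full[0, 13], full[0, 0], full[0, 1]])
        assert np.allclose(fast[0], ref, rtol=1e-6)

    def test_cspe_superposition_two_peaks(self, geom, optical_model):
        """Two separated deposits produce a two-peak 12x16 distribution."""
        a = geom.annulus.facet_apothem
        pts = np.array([[a - 4.0, 0.0, -8.0], [a - 4.0, 0.0, 8.0]])
        maps = expected_light_map(pts, [200.0, 311.0], optical_model, geom,
                                  facets=[0, 0])
        combined = maps.sum(axis=0)[1]  # primary facet, (4, 16) axial profile
        prof = combined.sum(axis=0)
        peaks = [i for i in range(1, 15)
                 if prof[i] > prof[i - 1] and prof[i] > prof[i + 1]]
        assert len(peaks) == 2


class TestSampledSignals:
    def test_zero_expectation_zero_dark(self):
        out = sample_signals(np.zeros((5, 14, 4, 16)), 1,
                             NoiseConfig(dark_mean=0.0))
        assert not out.any()

    def test_poisson_moments(self):
        rng = np.random.default_rng(4)
        expected = np.full((20_000,), 50.0)
        s = sample_signals(expected, rng, NoiseConfig(dark_mean=0.0))
        assert s.mean() == pytest.approx(50.0, rel=0.01)
        assert s.var() == pytest.approx(50.0, rel=0.05)

    def test_negative_expectation_rejected(self):
        with pytest.raises(ValueError):
            sample_signals(np.array([-1.0]), 0)

    def test_gain_map_fixed_per_scanner_seed(self, geom):
        g1 = make_gain_map(geom, NoiseConfig(scanner_seed=5))
        g2 = make_gain_map(geom, NoiseConfig(scanner_seed=5))
        g3 = make_gain_map(geom, NoiseConfig(scanner_seed=6))
        assert np.array_equal(g1, g2)
        assert not np.array_equal(g1, g3)
        assert g1.std() == pytest.approx(0.02, rel=0.2)

    def test_sampling_deterministic_at_fixed_seed(self, geom):
        exp = np.full((10, 14, 4, 16), 20.0)
        a = sample_signals(exp, 9, NoiseConfig())
        b = sample_signals(exp, 9, NoiseConfig())
        assert np.array_equal(a, b)
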