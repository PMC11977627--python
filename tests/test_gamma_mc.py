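"""Photon transport: Compton kinematics, attenuation, chain labelling."""

import numpy as np
import pytest
from scipy import stats

from annpet.gamma_mc import (CHAIN_LABELS, LYSOCrossSections, PhysicsConfig,
                             crystal_intervals, isotropic_directions,
                             path_survival, sample_klein_nishina,
                             simulate_events)
from annpet.phantoms import MousePhantomSpec, PointSourceSpec, make_attenuation_map


class TestKleinNishina:
    def test_compton_formula_anchor_points(self):
        # forward scatter keeps the energy; 180 deg at 511 keV -> 511/3
        E = 511.0
        _, Eb = sample_klein_nishina(E, 0, size=1000)
        assert np.all(Eb <= E + 1e-9)
        cos = np.cos(np.pi)
        assert E / (1 + (E / 511) * (1 - cos)) == pytest.approx(511 / 3)
        assert E / (1 + (E / 511) * (1 - np.cos(0.0))) == pytest.approx(E)

    def test_energy_angle_consistency(self):
        theta, E2 = sample_klein_nishina(511.0, 42, size=20_000)
        expect = 511.0 / (1 + (511 / 511) * (1 - np.cos(theta)))
        assert np.allclose(E2, expect)

    def test_angular_distribution_matches_integrated_cross_section(self):
        """Sampled cos(theta) histogram vs numerically integrated KN bins."""
        rng = np.random.default_rng(11)
        theta, _ = sample_klein_nishina(511.0, rng, size=200_000)
        edges = np.linspace(-1, 1, 41)
        obs, _ = np.histogram(np.cos(theta), bins=edges)

        def kn(c, a=1.0):
            r = 1.0 / (1.0 + a * (1.0 - c))
            return r**2 * (r + 1.0 / r - (1.0 - c**2))

        from scipy.integrate import quad
        probs = np.array([quad(kn, lo, hi)[0] for lo, hi in
                          zip(edges[:-1], edges[1:])])
        probs /= probs.sum()
        chi2, p = stats.chisquare(obs, probs * obs.sum())
        assert p > 0.01

    def test_invalid_energy(self):
        with pytest.raises(ValueError):
            sample_klein_nishina(-1.0, 0)


class TestCrossSections:
    def test_defaults_and_consistency(self):
        xs = LYSOCrossSections()
        assert xs.mu_total(511.0) == pytest.approx(0.087)
        assert xs.pe_fraction(511.0) == pytest.approx(0.33)
        E = np.linspace(50, 511, 50)
        assert np.allclose(xs.mu_pe(E) + xs.mu_cs(E), xs.mu_total(E))
        assert np.all(np.diff(xs.mu_total(E)) <= 0)


class TestPathSurvival:
    def test_closed_forms(self):
        mu = make_attenuation_map(MousePhantomSpec(), voxel_size=0.25)
        assert path_survival([0, 0, 0], [0, 0, 0], mu) == 1.0
        # 10 mm of water along the line source hole axis region: use
        # polyethylene body instead: y-traverse through center
        s = path_survival([0, -12.5, 0], [0, -2.5, 0], mu)
        assert s == pytest.approx(np.exp(-10 * 0.0093), rel=0.01)

    def test_multiplicative_over_subsegments(self):
        mu = make_attenuation_map(MousePhantomSpec(), voxel_size=0.5)
        a, b, c = [-20, 1, 2], [0, 1, 2], [18, 1, 2]
        s_ab = path_survival(a, b, mu)
        s_bc = path_survival(b, c, mu)
        s_ac = path_survival(a, c, mu)
        assert s_ac == pytest.approx(s_ab * s_bc, abs=1e-9)


class TestSimulation:
    def test_geometric_intercept_fraction(self, geom):
        """Both-photon bore-surface intercept fraction = 3.6/sqrt(3.6^2+3^2)."""
        rng = np.random.default_rng(1)
        d = isotropic_directions(100_000, rng)
        p = np.zeros_like(d)
        _, v1 = crystal_intervals(p, d, geom)
        _, v2 = crystal_intervals(p, -d, geom)
        frac = (v1.any(axis=1) & v2.any(axis=1)).mean()
        assert frac == pytest.approx(3.6 / np.hypot(3.6, 3.0), abs=0.005)

    def test_opaque_limit_interacts_at_inner_surface(self, geom):
        phys = PhysicsConfig(positron_range=False, acollinearity=False,
                             object_attenuation=False, mu_scale=1e6)
        src = PointSourceSpec()
        ev = simulate_events(src, geom, phys, 2000, 5)
        lab = ev.chain_label
        # every geometrically intercepting photon interacts: no photon that
        # hits the crystal escapes uninteracted, and interactions sit at the
        # bore surface
        hit = lab != 0
        r = np.hypot(ev.rec_pos[:, 0], ev.rec_pos[:, 1])
        first = ev.rec_order == 0
        assert np.allclose(r[first], 30.0, atol=1e-3)
        assert hit.mean() == pytest.approx(3.6 / np.hypot(3.6, 3.0), abs=0.02)

    def test_energy_conservation_per_chain(self, geom):
        phys = PhysicsConfig(positron_range=False, object_attenuation=False)
        ev = simulate_events(PointSourceSpec(), geom, phys, 5000, 9)
        dep = ev.deposited_energy()
        assert dep.max() <= 511.0 + 1e-6
        # terminated (PE-ended) chains deposit exactly 511 keV
        from annpet.gamma_mc import KIND_PE
        ends = np.zeros((ev.n_events, 2), bool)
        pe = ev.rec_kind == KIND_PE
        ends[ev.rec_event[pe], ev.rec_photon[pe].astype(int)] = True
        assert np.allclose(dep[ends], 511.0, atol=1e-9)

    def test_free_paths_exponential(self, geom):
        """Path lengths from the bore surface follow exp(mu_total) in LYSO."""
        phys = PhysicsConfig(positron_range=False, acollinearity=False,
                             object_attenuation=False)
        ev = simulate_events(PointSourceSpec(), geom, phys, 30_000, 13)
        first = ev.rec_order == 0
        pos = ev.rec_pos[first]
        evid = ev.rec_event[first]
        ph = ev.rec_photon[first]
        # depth along the ray from the bore entry point: for a central point
        # source the ray is radial in xy with known z slope; use distance
        # from entry r=30 shell along the straight path
        ann = ev.annihilation_points[evid]
        d = pos - ann
        L = np.linalg.norm(d, axis=1)
        r_entry = 30.0 / np.hypot(*(d[:, :2] / L[:, None]).T)  # path length to bore
        path_in_crystal = L - r_entry
        # exponential only below the available chord length; use a truncated
        # sample well inside (first 3 mm) against the conditional CDF
        sel = path_in_crystal < 3.0
        lam = 0.087
        cdf = lambda x: (1 - np.exp(-lam * x)) / (1 - np.exp(-lam * 3.0))
        stat, p = stats.kstest(path_in_crystal[sel], cdf)
        assert p > 0.01

    def test_labels_partition_and_pe_sweep(self, geom):
        src = PointSourceSpec()
        phys = PhysicsConfig(positron_range=False, object_attenuation=False)
        ev = simulate_events(src, geom, phys, 8000, 17)
        names = set(np.unique(ev.label_names()))
        assert names <= {"miss", "PE", "CSE", "CS-PE", "multi-CS"}
        assert {"miss", "PE", "CS-PE"} <= names
        # PE fraction -> 1 shifts chains toward pure PE
        fracs = []
        for pf in (0.33, 0.7, 0.999):
            p = PhysicsConfig(positron_range=False, object_attenuation=False,
                              pe_fraction_511=pf)
            e = simulate_events(src, geom, p, 4000, 23)
            lab = e.chain_label[e.chain_label != 0]
            fracs.append((lab == 1).mean())
        assert fracs[0] < fracs[1] < fracs[2]
        assert fracs[2] > 0.95

    def test_object_attenuation_lowers_yield(self, geom):
        """Coincidence yield in the mouse phantom < same source in air."""
        ph = MousePhantomSpec(hole_offset=0.0, hole_diameter=1.0)
        n = 6000
        on = simulate_events(ph, geom, PhysicsConfig(object_scatter=False), n, 31)
        off = simulate_events(ph, geom,
                              PhysicsConfig(object_attenuation=False), n, 31)
        both_on = (on.chain_label != 0).all(axis=1).sum()
        both_off = (off.chain_label != 0).all(axis=1).sum()
        assert both_on < both_off

    def test_determinism(self, geom):
        phys = PhysicsConfig()
        e1 = simulate_events(PointSourceSpec(), geom, phys, 500, 77)
        e2 = simulate_events(PointSourceSpec(), geom, phys, 500, 77)
        assert np.array_equal(e1.rec_pos, e2.rec_pos)
        assert np.array_equal(e1.chain_label, e2.chain_label)
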