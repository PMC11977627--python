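"""Harmonization, centre-of-mass baseline and the trainable positioner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from annpet.geometry import ScannerGeometry
from annpet.nn import NetConfig
from annpet.positioning import (DepthLUT, HarmonizationParams, com_position,
                                evaluate_positioner, harmonize,
                                make_pe_dataset, predict_position,
                                train_positioner, world_to_local)


class TestHarmonize:
    def test_uniform_distribution_stays_uniform(self):
        h, zero = harmonize(np.ones((12, 16)), HarmonizationParams(0.0025))
        assert np.allclose(h, 1.0)
        assert not zero

    def test_f_zero_is_pure_max_normalization(self):
        rng = np.random.default_rng(0)
        d = rng.random((12, 16))
        h, _ = harmonize(d, HarmonizationParams(0.0))
        assert np.allclose(h, d / d.max())
        # idempotent on its own output
        h2, _ = harmonize(h, HarmonizationParams(0.0))
        assert np.allclose(h2, h)

    def test_max_is_one_for_nonzero_input(self):
        rng = np.random.default_rng(1)
        d = rng.random((50, 12, 16))
        h, zero = harmonize(d)
        assert np.allclose(h.max(axis=(-2, -1)), 1.0)
        assert not zero.any()

    def test_all_zero_flagged(self):
        h, zero = harmonize(np.zeros((12, 16)))
        assert zero and not h.any()

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 1e4), seed=st.integers(0, 2**16))
    def test_scale_invariance(self, scale, seed):
        d = np.random.default_rng(seed).random((12, 16))
        h1, _ = harmonize(d)
        h2, _ = harmonize(scale * d)
        assert np.allclose(h1, h2, atol=1e-9)

    def test_invalid_f_factor(self):
        with pytest.raises(ValueError):
            HarmonizationParams(1.0 / 192.0)


class TestCenterOfMass:
    def test_symmetric_peak_centers(self, geom):
        d = np.zeros((12, 16))
        d[4:8, 7:9] = 1.0  # symmetric on the primary facet, centred in u and z
        pos, _ = com_position(d, 0, geom, DepthLUT())
        u, depth, z = world_to_local(pos, np.array([0]), geom)[0]
        assert u == pytest.approx(0.0, abs=1e-6)
        assert z == pytest.approx(0.0, abs=1e-6)

    def test_two_equal_peaks_average_out(self, geom):
        """Equal CS-PE peaks at +/- z centroid to z = 0 — the two-peak bias."""
        d = np.zeros((12, 16))
        d[5, 3] = 1.0
        d[5, 12] = 1.0  # symmetric about the axial centre (rows 7.5)
        pos, _ = com_position(d, 0, geom, DepthLUT())
        z = pos[0][2]
        assert z == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_distribution_rejected(self, geom):
        with pytest.raises(ValueError):
            com_position(np.zeros((12, 16)), 0, geom)

    def test_transaxial_bias_vanishes_at_high_statistics(self, geom,
                                                         optical_model):
        """On noise-free PE maps, CoM u-bias is small near the facet centre."""
        ds = make_pe_dataset(geom, optical_model, 800, 51)
        lut = DepthLUT.fit(ds["m2"], ds["local"][:, 1])
        pos, _ = com_position(ds["features"].reshape(-1, 12, 16),
                              ds["facet"], geom, lut)
        loc = world_to_local(pos, ds["facet"], geom)
        central = np.abs(ds["local"][:, 0]) < 4.0
        bias = (loc[central, 0] - ds["local"][central, 0]).mean()
        assert abs(bias) < 0.3


@pytest.fixture(scope="module")
def pe_data(geom, optical_model):
    return make_pe_dataset(geom, optical_model, 12_000, 71)


@pytest.fixture(scope="module")
def trained(pe_data):
    tr = {k: pe_data[k][:10_000] for k in ("features", "local")}
    return train_positioner(tr, NetConfig(epochs=8), seed=3)


class TestPositioner:
    def test_loss_decreases(self, trained):
        h = trained.loss_history
        assert len(h) == 8
        assert h[-1] < h[0]

    def test_training_deterministic(self, pe_data):
        tr = {k: pe_data[k][:2000] for k in ("features", "local")}
        m1 = train_positioner(tr, NetConfig(epochs=2), seed=5)
        m2 = train_positioner(tr, NetConfig(epochs=2), seed=5)
        assert m1.loss_history == m2.loss_history
        assert all(np.array_equal(a, b) for a, b in
                   zip(m1.net.params, m2.net.params))

    def test_memorizes_single_position(self, geom, optical_model):
        """Noiseless single-position data is fit to < 0.1 mm RMSE."""
        ds = make_pe_dataset(geom, optical_model, 4, 9)
        feats = np.tile(ds["features"][:1], (256, 1))
        local = np.tile(ds["local"][:1], (256, 1))
        m = train_positioner({"features": feats, "local": local},
                             NetConfig(epochs=30, batch_size=64), seed=0)
        pred = m.predict_local(feats[:8])
        rmse = np.sqrt(((pred - local[:8]) ** 2).sum(axis=1).mean())
        assert rmse < 0.1

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_positioner({"features": np.zeros((0, 192)),
                              "local": np.zeros((0, 3))})

    def test_predictions_inside_annulus_and_deterministic(self, geom, trained,
                                                          pe_data):
        x = pe_data["features"][10_000:10_500]
        f = pe_data["facet"][10_000:10_500]
        p1, flags = predict_position(trained, x, f, geom)
        p2, _ = predict_position(trained, x, f, geom)
        assert np.array_equal(p1, p2)
        assert geom.contains(p1).all()

    def test_shape_mismatch_rejected(self, geom, trained):
        with pytest.raises(ValueError, match="192"):
            predict_position(trained, np.zeros((3, 100)), [0, 0, 0], geom)

    def test_model_roundtrip(self, tmp_path, trained, pe_data, geom):
        path = str(tmp_path / "model.npz")
        trained.save(path)
        from annpet.positioning import PositionerModel

        m2 = PositionerModel.load(path)
        x = pe_data["features"][:64]
        assert np.allclose(m2.predict_local(x), trained.predict_local(x))

    def test_beats_com_on_held_out_pe(self, geom, trained, pe_data):
        """The network outperforms centre-of-mass on every local axis."""
        test = {k: pe_data[k][10_000:] for k in pe_data}
        lut = DepthLUT.fit(pe_data["m2"][:10_000],
                           pe_data["local"][:10_000, 1])
        pred, _ = predict_position(trained, test["features"], test["facet"], geom)
        nn_err = world_to_local(pred, test["facet"], geom) - test["local"]
        com, _ = com_position(test["features"].reshape(-1, 12, 16),
                              test["facet"], geom, lut)
        com_err = world_to_local(com, test["facet"], geom) - test["local"]
        nn_rmse = np.sqrt((nn_err**2).mean(axis=0))
        com_rmse = np.sqrt((com_err**2).mean(axis=0))
        assert (nn_rmse <= com_rmse).all()


class TestEvaluation:
    def test_perfect_oracle_zero_rmse(self, geom, pe_data):
        test = {k: pe_data[k][:500] for k in pe_data}

        def oracle(features, facets):
            return test["world"][:len(facets)]

        rep = evaluate_positioner(oracle, test, geom)
        assert rep["strata"]["all"]["rmse_3d"] == pytest.approx(0.0, abs=1e-9)
        assert rep["n_total"] == 500

    def test_cspe_stratum_harder_than_pe(self, geom, optical_model, noise_cfg,
                                         trained):
        """CS-PE two-peak ambiguity inflates that stratum's error."""
        from annpet.daq import DAQConfig, find_coincidences, make_singles
        from annpet.gamma_mc import PhysicsConfig, simulate_events
        from annpet.phantoms import PointSourceSpec
        from annpet.positioning import dataset_from_batch

        phys = PhysicsConfig(positron_range=False, object_attenuation=False)
        batch = simulate_events(PointSourceSpec(), geom, phys, 12_000, 303)
        singles = make_singles(batch, optical_model, geom, DAQConfig(),
                               noise_cfg, 304)
        coinc = find_coincidences(singles, DAQConfig(), geom)
        ds = dataset_from_batch(batch, coinc, geom)

        def net(features, facets):
            return predict_position(trained, features, facets, geom)[0]

        rep = evaluate_positioner(net, ds, geom)
        assert rep["strata"]["CS-PE"]["rmse_3d"] \
            >= rep["strata"]["PE"]["rmse_3d"]
        assert "miss" not in rep["strata"] or rep["strata"]["miss"]["n"] == 0
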