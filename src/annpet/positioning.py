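"""Event positioning from 12 x 16 scintillation-light distributions.

Pipeline: *harmonization* (subtract an f-factor fraction of the pixel sum,
clamp at zero, normalize the maximum to 1 — the bridge between measured and
simulation-scaled distributions), then either

* a centre-of-mass baseline (transaxial/axial centroid plus a second-moment
  depth lookup calibrated on simulated photoelectric events), or
* a trainable residual neural-network positioner working in facet-local
  coordinates (u across the facet, d depth below the sensor plane, z axial),
  trained on simulated distributions whose label is the FIRST interaction
  of the photon chain — for CS-PE chains the Compton vertex, the correct
  LOR endpoint.

Estimates are clamped into the annulus solid and flagged when clamping was
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .daq import assemble_distribution
from .geometry import ScannerGeometry
from .nn import NetConfig, ResidualMLP
from .optics import NoiseConfig, OpticalModel, expected_light_map, sample_signals

__all__ = [
    "HarmonizationParams",
    "harmonize",
    "DepthLUT",
    "com_position",
    "PositionerModel",
    "make_pe_dataset",
    "dataset_from_batch",
    "train_positioner",
    "predict_position",
    "evaluate_positioner",
]


@dataclass(frozen=True)
class HarmonizationParams:
    f_factor: float = 0.0025

    def __post_init__(self):
        if not 0.0 <= self.f_factor < 1.0 / 192.0:
            raise ValueError("f_factor must be in [0, 1/192) so a uniform "
                             "map is not fully nulled")


def harmonize(dist: np.ndarray, params: HarmonizationParams | None = None):
    """f-factor subtraction (clamped at zero) followed by max-normalization.

    Accepts (..., 12, 16) arrays.  Returns ``(harmonized, all_zero_flags)``;
    all-zero inputs come back all-zero with their flag set.  The output
    maximum is exactly 1 for any non-zero input, and the transform is
    invariant to positive rescaling of the input.
    """
    params = params or HarmonizationParams()
    d = np.asarray(dist, float)
    total = d.sum(axis=(-2, -1), keepdims=True)
    out = np.maximum(d - params.f_factor * total, 0.0)
    peak = out.max(axis=(-2, -1), keepdims=True)
    zero = peak[..., 0, 0] <= 0
    out = np.where(peak > 0, out / np.where(peak > 0, peak, 1.0), 0.0)
    return out, zero


# ---------------------------------------------------------------------------
# centre-of-mass baseline

# transaxial arc coordinate of the 12 columns (3 facets x 4 pixels) and the
# axial coordinate of the 16 rows, facet-local mm
def _unrolled_coords(geom: ScannerGeometry):
    pitch = geom.sensors.pixel_pitch
    w = geom.annulus.facet_width
    col = np.arange(12)
    t = (col % 4 - 1.5) * pitch + (col // 4 - 1) * w
    row = np.arange(16)
    z = (row - 7.5) * pitch
    return t, z


@dataclass
class DepthLUT:
    """Monotone lookup from distribution second moment to mean depth.

    Calibrated on simulated photoelectric events; ``depth`` is measured from
    the sensor plane inward.
    """

    m2_grid: np.ndarray = None
    depth_grid: np.ndarray = None
    default_depth: float = 5.0

    def __call__(self, m2) -> np.ndarray:
        m2 = np.asarray(m2, float)
        if self.m2_grid is None:
            return np.full(m2.shape, self.default_depth)
        return np.interp(m2, self.m2_grid, self.depth_grid)

    @classmethod
    def fit(cls, m2: np.ndarray, depth: np.ndarray, n_bins: int = 24) -> "DepthLUT":
        qs = np.quantile(m2, np.linspace(0, 1, n_bins + 1))
        centers, means = [], []
        for lo, hi in zip(qs[:-1], qs[1:]):
            sel = (m2 >= lo) & (m2 <= hi)
            if sel.sum() >= 5:
                centers.append(m2[sel].mean())
                means.append(depth[sel].mean())
        return cls(np.asarray(centers), np.asarray(means),
                   default_depth=float(np.mean(depth)))


def _moments(dist: np.ndarray, geom: ScannerGeometry):
    """Weighted centroid (t, z) and radial second moment of distributions."""
    t, z = _unrolled_coords(geom)
    w = np.asarray(dist, float)
    tot = w.sum(axis=(-2, -1))
    if np.any(tot <= 0):
        raise ValueError("all-zero distribution has no centroid")
    tc = (w.sum(axis=-1) @ t) / tot
    zc = (w.sum(axis=-2) @ z) / tot
    dt2 = (w.sum(axis=-1) * (t[None, :] - tc[:, None]) ** 2).sum(axis=-1)
    dz2 = (w.sum(axis=-2) * (z[None, :] - zc[:, None]) ** 2).sum(axis=-1)
    m2 = (dt2 + dz2) / tot
    return tc, zc, m2


def com_position(dist, primary, geom: ScannerGeometry,
                 depth_lut: DepthLUT | None = None):
    """Centre-of-mass position estimate for harmonized distributions.

    ``dist``: (m, 12, 16); ``primary``: (m,) facet ids.  Returns
    ``(positions (m, 3) world mm, clamped flags)``.
    """
    dist = np.atleast_2d(np.asarray(dist, float))
    if dist.ndim == 2:
        dist = dist[None]
    primary = np.atleast_1d(np.asarray(primary, int))
    lut = depth_lut or DepthLUT()
    tc, zc, m2 = _moments(dist, geom)
    depth = lut(m2)
    local = np.stack([tc, depth, zc], axis=1)
    return local_to_world(local, primary, geom)


def local_to_world(local: np.ndarray, primary: np.ndarray,
                   geom: ScannerGeometry):
    """(u, depth-below-plane, z) in a facet frame -> clamped world points."""
    u, d, z = local[:, 0], local[:, 1], local[:, 2]
    pts = (geom.origins[primary]
           + u[:, None] * geom.u_axes[primary]
           - d[:, None] * geom.normals[primary])
    pts[:, 2] = z
    return geom.clamp_to_annulus(pts)


def world_to_local(points: np.ndarray, facet: np.ndarray,
                   geom: ScannerGeometry) -> np.ndarray:
    rel = points - geom.origins[facet]
    u = np.einsum("ij,ij->i", rel, geom.u_axes[facet])
    d = -np.einsum("ij,ij->i", rel, geom.normals[facet])
    return np.stack([u, d, points[:, 2]], axis=1)


# ---------------------------------------------------------------------------
# datasets


def _uniform_crystal_points(geom: ScannerGeometry, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the scintillator solid (rejection from the shell)."""
    a = geom.annulus
    out = np.empty((0, 3))
    while out.shape[0] < n:
        k = int((n - out.shape[0]) * 1.8) + 16
        r = np.sqrt(rng.uniform(a.inner_radius**2, a.max_outer_radius**2, k))
        th = rng.uniform(0, 2 * np.pi, k)
        z = rng.uniform(-a.length / 2, a.length / 2, k)
        pts = np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)
        pts = pts[geom.contains(pts)]
        out = np.vstack([out, pts])
    return out[:n]


def make_pe_dataset(geom: ScannerGeometry, model: OpticalModel, n: int, rng,
                    noise: NoiseConfig | None = None,
                    harm: HarmonizationParams | None = None,
                    energy_kev: float = 511.0) -> dict:
    """Single-site photoelectric training/evaluation set.

    Interaction points are uniform over the crystal volume.  Distributions
    are built around the point's sector facet; with a ``noise`` config the
    maps are Poisson-sampled measured amplitudes, otherwise noise-free
    expectations (the simulation-side training convention).

    Returns a dict with ``features`` (m, 192) harmonized flattened maps,
    ``local`` (m, 3) facet-local (u, depth, z) labels, ``facet``, ``world``
    and ``m2`` second moments.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pts = _uniform_crystal_points(geom, n, rng)
    facet = np.atleast_1d(geom.locate_point(pts)[0])
    maps3 = expected_light_map(pts, np.full(n, energy_kev), model, geom,
                               facets=facet)
    if noise is not None:
        from .optics import make_gain_map

        nf = geom.n_facets
        sel = np.stack([(facet - 1) % nf, facet, (facet + 1) % nf], axis=1)
        maps3 = sample_signals(maps3, rng, noise, make_gain_map(geom, noise)[sel])
    dists = assemble_distribution(maps3)
    feats, zero = harmonize(dists, harm)
    local = world_to_local(pts, facet, geom)
    keep = ~zero
    tc, zc, m2 = _moments(feats[keep], geom)
    return {
        "features": feats[keep].reshape(-1, 192),
        "local": local[keep],
        "facet": facet[keep],
        "world": pts[keep],
        "m2": m2,
        "label": np.full(int(keep.sum()), 1, np.int8),  # PE
    }


def dataset_from_batch(batch, coinc, geom: ScannerGeometry,
                       harm: HarmonizationParams | None = None) -> dict:
    """Labelled samples from DAQ coincidences with truth links.

    Each prompt contributes its two distributions; the label position is the
    first interaction of the linked photon chain, in the primary facet's
    local frame.  Samples whose truth link is missing are dropped.
    """
    pos_first, ok = batch.first_interactions()
    feats, locals_, facets, labels, world = [], [], [], [], []
    for side, fac in ((0, coinc.primary), (1, coinc.secondary)):
        ev = coinc.truth_event[:, side]
        ph = coinc.truth_photon[:, side]
        good = (ev >= 0) & ok[np.maximum(ev, 0), ph]
        d, zero = harmonize(coinc.dists[good, side], harm)
        keep = ~zero
        f = fac[good][keep]
        p = pos_first[ev[good][keep], ph[good][keep]]
        feats.append(d[keep].reshape(-1, 192))
        locals_.append(world_to_local(p, f, geom))
        facets.append(f)
        world.append(p)
        labels.append(batch.chain_label[ev[good][keep], ph[good][keep]])
    return {
        "features": np.vstack(feats),
        "local": np.vstack(locals_),
        "facet": np.concatenate(facets),
        "world": np.vstack(world),
        "label": np.concatenate(labels),
    }


# ---------------------------------------------------------------------------
# trainable positioner


@dataclass
class PositionerModel:
    """Trained residual-network positioner plus its metadata."""

    net: ResidualMLP
    net_config: NetConfig
    target_mean: np.ndarray
    target_std: np.ndarray
    n_train: int
    seed: int
    loss_history: list = field(default_factory=list)

    def predict_local(self, features: np.ndarray) -> np.ndarray:
        y = self.net.predict(np.asarray(features, float))
        return y * self.target_std + self.target_mean

    def save(self, path: str) -> None:
        import json

        meta = {"hidden": self.net_config.hidden,
                "n_blocks": self.net_config.n_blocks,
                "epochs": self.net_config.epochs,
                "batch_size": self.net_config.batch_size,
                "learning_rate": self.net_config.learning_rate,
                "n_train": self.n_train, "seed": self.seed,
                "loss_history": self.loss_history}
        np.savez(path, meta=json.dumps(meta),
                 target_mean=self.target_mean, target_std=self.target_std,
                 **self.net.state_dict())

    @classmethod
    def load(cls, path: str) -> "PositionerModel":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cfg = NetConfig(hidden=meta["hidden"], n_blocks=meta["n_blocks"],
                            epochs=meta["epochs"], batch_size=meta["batch_size"],
                            learning_rate=meta["learning_rate"])
            net = ResidualMLP(192, 3, cfg, np.random.default_rng(0))
            net.load_state_dict({k: z[k] for k in z.files if k.startswith("p")})
            return cls(net, cfg, z["target_mean"], z["target_std"],
                       meta["n_train"], meta["seed"], meta["loss_history"])


def train_positioner(dataset: dict, cfg: NetConfig | None = None,
                     seed: int = 0, verbose: bool = False) -> PositionerModel:
    """Train the residual-network positioner on (features, local) pairs."""
    cfg = cfg or NetConfig()
    x = np.asarray(dataset["features"], float)
    y = np.asarray(dataset["local"], float)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise ValueError("features/labels size mismatch")
    mu = y.mean(axis=0)
    sd = y.std(axis=0)
    sd = np.where(sd > 1e-9, sd, 1.0)
    rng = np.random.default_rng(seed)
    net = ResidualMLP(x.shape[1], y.shape[1], cfg, rng)
    history = net.fit(x, (y - mu) / sd, rng, verbose=verbose)
    return PositionerModel(net, cfg, mu, sd, x.shape[0], seed, history)


def predict_position(model: PositionerModel, dist, primary,
                     geom: ScannerGeometry):
    """Network position estimate, clamped into the annulus.

    ``dist``: harmonized (m, 12, 16) or flat (m, 192); returns
    ``(world positions (m, 3), clamped flags)``.
    """
    d = np.asarray(dist, float)
    if d.ndim >= 2 and d.shape[-1] == 16:
        d = d.reshape(-1, 192)
    if d.ndim == 1:
        d = d[None]
    if d.shape[1] != 192:
        raise ValueError(f"expected 192 features per sample, got {d.shape[1]}")
    local = model.predict_local(d)
    return local_to_world(local, np.atleast_1d(np.asarray(primary, int)), geom)


def evaluate_positioner(predict_fn, dataset: dict,
                        geom: ScannerGeometry) -> dict:
    """Per-axis bias and RMSE, stratified by interaction-chain label.

    ``predict_fn(features, facets) -> world positions``; errors are reported
    in facet-local axes (u: transaxial, d: radial depth, z: axial), where
    the CS-PE two-peak ambiguity shows up as an inflated stratum RMSE.
    """
    from .gamma_mc import CHAIN_LABELS

    pred_world = predict_fn(dataset["features"], dataset["facet"])
    pred_local = world_to_local(pred_world, dataset["facet"], geom)
    err = pred_local - dataset["local"]
    report = {"n_total": int(err.shape[0]), "strata": {}}
    axes = ("u", "d", "z")
    strata = {"all": np.ones(err.shape[0], bool)}
    for code, name in CHAIN_LABELS.items():
        mask = dataset["label"] == code
        if mask.any():
            strata[name] = mask
    for name, mask in strata.items():
        e = err[mask]
        report["strata"][name] = {
            "n": int(mask.sum()),
            "bias": {a: float(e[:, i].mean()) for i, a in enumerate(axes)},
            "rmse": {a: float(np.sqrt((e[:, i] ** 2).mean())) for i, a in enumerate(axes)},
            "rmse_3d": float(np.sqrt((e**2).sum(axis=1).mean())),
        }
    assert sum(v["n"] for k, v in report["strata"].items() if k != "all") \
        == report["n_total"]
    return report
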