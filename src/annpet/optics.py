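"""Parametric scintillation-light model for the monolithic annulus.

Replaces optical-photon ray tracing with a solid-angle + single mirror-image
model: the expected signal on a SiPM pixel from an energy deposition is

    light_yield * E_dep * eps * [Omega(x, pix) + rho * Omega(x', pix)] / 4pi
                                                        * exp(-r / lambda)

where ``Omega`` is the exact solid angle of the 4 mm active pixel square seen
from the interaction point, ``x'`` is the point mirrored across the specular
inner bore surface (reflectance ``rho``), ``r`` the optical path and
``lambda`` a bulk attenuation length.  The black-painted annulus ends are
absorptive, hence no axial mirror term.  Expectations are linear in deposited
energy, so the two interaction sites of a CS-PE chain superpose into the
characteristic two-peak 12 x 16 distribution.

Amplitudes are in photoelectron (p.e.) units throughout; sensor dead space is
modelled by integrating the solid angle over the 4 mm active square only
(4.4 mm pitch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScannerGeometry

__all__ = [
    "OpticalModel",
    "NoiseConfig",
    "expected_light_map",
    "chain_expected_maps",
    "sample_signals",
    "make_gain_map",
    "three_facet_fraction",
]


@dataclass(frozen=True)
class OpticalModel:
    """Light generation / collection parameters (all config-exposed)."""

    light_yield: float = 29.0            # photons / keV
    collection_efficiency: float = 0.25  # folds optical coupling and PDE
    attenuation_length: float = 200.0    # mm
    inner_reflectance: float = 0.95      # specular inner bore surface
    end_reflectance: float = 0.0         # absorptive painted ends
    n_crystal: float = 1.82              # LYSO refractive index
    n_coupling: float = 1.41             # silicone coupling layer
    mirror_facet_range: int = 1          # bore-mirror term valid within +/- k facets

    def __post_init__(self):
        for f in ("collection_efficiency", "inner_reflectance", "end_reflectance"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.light_yield < 0 or self.attenuation_length <= 0:
            raise ValueError("light_yield >= 0 and attenuation_length > 0 required")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-sensor gain spread and dark-count floor."""

    gain_sigma: float = 0.02     # lognormal sigma of fixed per-pixel gains
    dark_mean: float = 0.5       # mean dark p.e. per pixel per event window
    scanner_seed: int = 12345    # fixes the gain map for a 'scanner build'


def _pixel_corners(geom: ScannerGeometry) -> np.ndarray:
    """(nf, 4, 16, 4, 3) world corners of the active pixel squares (cached)."""
    cached = getattr(geom, "_pixel_corners", None)
    if cached is not None:
        return cached
    half = geom.sensors.pixel_size / 2.0
    uu, vv = geom.pixel_uv  # (4, 16) facet-local coords
    nf = geom.n_facets
    du = np.array([-half, half, half, -half])
    dv = np.array([-half, -half, half, half])
    u = uu[None, :, :, None] + du[None, None, None, :]
    v = vv[None, :, :, None] + dv[None, None, None, :]
    corners = (
        geom.origins[:, None, None, None, :]
        + u[..., None] * geom.u_axes[:, None, None, None, :]
        + v[..., None] * geom.v_axes[:, None, None, None, :]
    )
    corners = np.broadcast_to(corners, (nf, uu.shape[0], uu.shape[1], 4, 3)).copy()
    geom._pixel_corners = corners
    return corners


def _triangle_solid_angle(R1, R2, R3):
    """Van Oosterom-Strackee solid angle of triangles seen from the origin."""
    r1 = np.linalg.norm(R1, axis=-1)
    r2 = np.linalg.norm(R2, axis=-1)
    r3 = np.linalg.norm(R3, axis=-1)
    num = np.abs(np.einsum("...i,...i->...", R1, np.cross(R2, R3)))
    den = (
        r1 * r2 * r3
        + np.einsum("...i,...i->...", R1, R2) * r3
        + np.einsum("...i,...i->...", R1, R3) * r2
        + np.einsum("...i,...i->...", R2, R3) * r1
    )
    return 2.0 * np.arctan2(num, den)


def _rect_solid_angle(points, corners):
    """Solid angle of rectangles from viewpoints.

    points: (m, 3); corners: (..., 4, 3) -> returns (m, ...).
    """
    extra = corners.ndim - 2  # leading rectangle axes
    view = points.reshape(points.shape[0], *([1] * extra), 3)
    rel = corners[None, ...] - view[..., None, :]
    # rel shape: (m, ..., 4, 3)
    c0, c1, c2, c3 = (rel[..., k, :] for k in range(4))
    return _triangle_solid_angle(c0, c1, c2) + _triangle_solid_angle(c0, c2, c3)


def _fresnel_transmission(cos_i, n1: float, n2: float) -> np.ndarray:
    """Unpolarized Fresnel transmittance crystal -> coupling layer.

    Light arriving at the sensor face beyond the total-internal-reflection
    critical angle (asin(n2/n1)) is not collected; this is what confines the
    detected light of an event to a few facets despite the optically
    continuous annulus.
    """
    cos_i = np.clip(np.abs(cos_i), 0.0, 1.0)
    sin_i2 = 1.0 - cos_i**2
    sin_t2 = (n1 / n2) ** 2 * sin_i2
    tir = sin_t2 >= 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t2, 0.0, 1.0))
    a = n1 * cos_i
    b = n2 * cos_t
    rs = ((a - b) / np.where(a + b > 0, a + b, 1.0)) ** 2
    c = n1 * cos_t
    d = n2 * cos_i
    rp = ((c - d) / np.where(c + d > 0, c + d, 1.0)) ** 2
    return np.where(tir, 0.0, 1.0 - 0.5 * (rs + rp))


def _bore_blocked(points, targets, geom: ScannerGeometry) -> np.ndarray:
    """True where the straight path from point to target crosses the bore.

    The interaction and the sensor pixel both sit in the crystal (r >= bore
    radius); a chord whose transaxial closest approach dips inside the bore
    cylinder would have to leave the crystal through the specular inner
    reflector, so its direct contribution is suppressed.

    points: (m, 3); targets: (m, ..., 3) -> bool of targets' shape[:-1].
    """
    r_in = geom.annulus.inner_radius
    extra = targets.ndim - 2
    p = points.reshape(points.shape[0], *([1] * extra), 3)[..., :2]
    q = targets[..., :2]
    d = q - p
    dd = np.einsum("...i,...i->...", d, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstar = -np.einsum("...i,...i->...", p, d) / np.where(dd > 0, dd, 1.0)
    tstar = np.clip(tstar, 0.0, 1.0)
    closest = p + tstar[..., None] * d
    return np.einsum("...i,...i->...", closest, closest) < (r_in - 1e-9) ** 2


def _mirror_points(points: np.ndarray, geom: ScannerGeometry) -> np.ndarray:
    """Reflect points across the inner cylindrical bore surface (radially)."""
    r_in = geom.annulus.inner_radius
    out = points.copy()
    rxy = np.hypot(points[:, 0], points[:, 1])
    safe = rxy > 1e-9
    scale = np.where(safe, (2.0 * r_in - rxy) / np.where(safe, rxy, 1.0), 1.0)
    out[:, 0] *= scale
    out[:, 1] *= scale
    return out


def expected_light_map(
    positions,
    energies,
    model: OpticalModel,
    geom: ScannerGeometry,
    facets=None,
    chunk: int = 256,
) -> np.ndarray:
    """Noise-free expected p.e. per pixel for point energy depositions.

    positions: (m, 3) mm inside the scintillator; energies: (m,) keV.
    Returns (m, nf, 4, 16) float32, or (m, 3, 4, 16) when ``facets`` gives a
    per-deposition primary facet (the map then covers facet-1, facet, facet+1
    in increasing-azimuth order).
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    energies = np.atleast_1d(np.asarray(energies, float))
    m = positions.shape[0]
    inside = geom.contains(positions)
    if not np.all(np.atleast_1d(inside)):
        raise ValueError("interaction position outside the scintillator solid")

    corners = _pixel_corners(geom)  # (nf, 4, 16, 4, 3)
    centers = geom.pixel_centers    # (nf, 4, 16, 3)
    nf = geom.n_facets
    scale = model.light_yield * model.collection_efficiency / (4.0 * np.pi)
    mirrors = _mirror_points(positions, geom)

    if facets is not None:
        facets = np.asarray(facets, int)
        sel = np.stack([(facets - 1) % nf, facets, (facets + 1) % nf], axis=1)
        out = np.empty((m, 3, corners.shape[1], corners.shape[2]), np.float32)
    else:
        out = np.empty((m, nf, corners.shape[1], corners.shape[2]), np.float32)

    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        pts = positions[lo:hi]
        mir = mirrors[lo:hi]
        if facets is not None:
            cset = corners[sel[lo:hi]]        # (k, 3, 4, 16, 4, 3)
            ccen = centers[sel[lo:hi]]        # (k, 3, 4, 16, 3)
            nrm = geom.normals[sel[lo:hi]]    # (k, 3, 3)
            rel = cset - pts[:, None, None, None, None, :]
            omega = (_triangle_solid_angle(rel[..., 0, :], rel[..., 1, :], rel[..., 2, :])
                     + _triangle_solid_angle(rel[..., 0, :], rel[..., 2, :], rel[..., 3, :]))
            relm = cset - mir[:, None, None, None, None, :]
            omega_m = (_triangle_solid_angle(relm[..., 0, :], relm[..., 1, :], relm[..., 2, :])
                       + _triangle_solid_angle(relm[..., 0, :], relm[..., 2, :], relm[..., 3, :]))
            dvec = ccen - pts[:, None, None, None, :]
            dvec_m = ccen - mir[:, None, None, None, :]
            r = np.linalg.norm(dvec, axis=-1)
            rm = np.linalg.norm(dvec_m, axis=-1)
            nrm_b = nrm[:, :, None, None, :]
            omega = np.where(_bore_blocked(pts, ccen, geom), 0.0, omega)
        else:
            omega = _rect_solid_angle(pts, corners)
            omega_m = _rect_solid_angle(mir, corners)
            dvec = centers[None] - pts[:, None, None, None, :]
            dvec_m = centers[None] - mir[:, None, None, None, :]
            r = np.linalg.norm(dvec, axis=-1)
            rm = np.linalg.norm(dvec_m, axis=-1)
            nrm_b = geom.normals[None, :, None, None, :]
            tgt = np.broadcast_to(centers[None], (pts.shape[0],) + centers.shape)
            omega = np.where(_bore_blocked(pts, tgt, geom), 0.0, omega)
            # the convex bore mirror is modelled as locally flat; its image
            # is only meaningful for sensors azimuthally near the source
            sector = np.argmax(pts @ geom.normals.T, axis=1)
            off = (np.arange(nf)[None, :] - sector[:, None]) % nf
            near = (off <= model.mirror_facet_range) | (off >= nf - model.mirror_facet_range)
            omega_m = np.where(near[:, :, None, None], omega_m, 0.0)
        cos_i = np.einsum("...i,...i->...", dvec, nrm_b) / np.where(r > 0, r, 1.0)
        cos_i_m = np.einsum("...i,...i->...", dvec_m, nrm_b) / np.where(rm > 0, rm, 1.0)
        omega = omega * _fresnel_transmission(cos_i, model.n_crystal, model.n_coupling)
        omega_m = omega_m * _fresnel_transmission(cos_i_m, model.n_crystal, model.n_coupling)
        att = np.exp(-r / model.attenuation_length)
        att_m = np.exp(-rm / model.attenuation_length)
        e = energies[lo:hi].reshape(-1, *([1] * (omega.ndim - 1)))
        out[lo:hi] = (scale * e * (omega * att
                                   + model.inner_reflectance * omega_m * att_m)
                      ).astype(np.float32)
    return out


def chain_expected_maps(batch, model: OpticalModel, geom: ScannerGeometry):
    """Summed expected light map per (event, photon) chain of an EventBatch.

    Returns ``(keys, maps)``: keys (K, 2) int array of (event, photon) pairs
    with at least one interaction, maps (K, nf, 4, 16) float32.
    """
    if batch.rec_event.size == 0:
        return np.zeros((0, 2), int), np.zeros((0, geom.n_facets, 4, 16), np.float32)
    per_rec = expected_light_map(batch.rec_pos, batch.rec_edep, model, geom)
    pair_id = batch.rec_event * 2 + batch.rec_photon
    keys, inv = np.unique(pair_id, return_inverse=True)
    maps = np.zeros((keys.size,) + per_rec.shape[1:], np.float32)
    np.add.at(maps, inv, per_rec)
    out_keys = np.stack([keys // 2, keys % 2], axis=1)
    return out_keys, maps


def make_gain_map(geom: ScannerGeometry, noise: NoiseConfig) -> np.ndarray:
    """Fixed per-pixel lognormal gain factors for one 'scanner build'."""
    rng = np.random.default_rng(noise.scanner_seed)
    shape = (geom.n_facets,) + geom.pixel_centers.shape[1:3]
    return rng.lognormal(mean=0.0, sigma=noise.gain_sigma, size=shape)


def sample_signals(expected, rng, noise: NoiseConfig | None = None,
                   gain_map: np.ndarray | None = None) -> np.ndarray:
    """Sample measured amplitudes: Poisson(expected) * gain + dark counts."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    noise = noise or NoiseConfig()
    expected = np.asarray(expected)
    if np.any(expected < 0):
        raise ValueError("expected signal must be non-negative")
    counts = rng.poisson(expected).astype(np.float32)
    if gain_map is not None:
        counts = counts * gain_map.astype(np.float32)
    if noise.dark_mean > 0:
        counts = counts + rng.poisson(noise.dark_mean, size=counts.shape)
    return counts


def three_facet_fraction(maps: np.ndarray, primary=None) -> np.ndarray:
    """Fraction of total expected light within the primary facet +/- 1.

    maps: (m, nf, 4, 16); primary defaults to the facet with the largest sum.
    """
    maps = np.asarray(maps, float)
    per_facet = maps.sum(axis=(2, 3))
    nf = per_facet.shape[1]
    if primary is None:
        primary = np.argmax(per_facet, axis=1)
    primary = np.asarray(primary, int)
    idx = np.arange(per_facet.shape[0])
    tri = (per_facet[idx, primary]
           + per_facet[idx, (primary - 1) % nf]
           + per_facet[idx, (primary + 1) % nf])
    total = per_facet.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, tri / total, 0.0)
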