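"""Annihilation-photon Monte Carlo in the LYSO annulus.

Reduced-physics transport: back-to-back 511 keV pairs (Gaussian
acollinearity blur), analytic attenuation / single-Compton scatter in the
object, exponential free paths in the crystal from tabulated LYSO cross
sections, photoelectric vs Compton branching, Klein-Nishina scatter
kinematics, and a 50 keV tracking cutoff.  Each photon yields a labelled
interaction chain: PE, CSE (Compton + escape), CS-PE (Compton followed by
photoelectric absorption of the scattered photon, the two-peak case),
multi-CS, or miss.

Rayleigh scattering, fluorescence escape and Doppler broadening are omitted:
they are second order for the positioning/reconstruction chain this package
exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry
from .phantoms import object_intervals, sample_emissions

__all__ = [
    "LYSOCrossSections",
    "PhysicsConfig",
    "EventBatch",
    "sample_klein_nishina",
    "path_survival",
    "simulate_events",
    "crystal_intervals",
    "CHAIN_LABELS",
]

C_MM_PER_NS = 299.792458

KIND_PE = 0
KIND_CS = 1

LABEL_MISS = 0
LABEL_PE = 1
LABEL_CSE = 2
LABEL_CSPE = 3
LABEL_MULTI = 4
CHAIN_LABELS = {LABEL_MISS: "miss", LABEL_PE: "PE", LABEL_CSE: "CSE",
                LABEL_CSPE: "CS-PE", LABEL_MULTI: "multi-CS"}


class LYSOCrossSections:
    """Tabulated LYSO attenuation, log-log interpolated over 50-511 keV.

    The table is a compact parametric stand-in anchored at the 511 keV
    values (total 0.087/mm, photoelectric fraction 0.33); lower-energy points
    are literature-consistent approximations.  ``mu_pe + mu_cs = mu_total``
    holds at every tabulated energy by construction.
    """

    _E = np.array([50.0, 80.0, 100.0, 150.0, 200.0, 300.0, 400.0, 511.0])
    _MU_TOT = np.array([4.00, 1.90, 1.20, 0.500, 0.290, 0.155, 0.110, 0.087])
    _PE_FRAC = np.array([0.95, 0.90, 0.87, 0.76, 0.64, 0.48, 0.39, 0.33])

    def __init__(self, scale: float = 1.0, pe_fraction_511: float | None = None):
        self.scale = scale
        self._pe_frac = self._PE_FRAC.copy()
        if pe_fraction_511 is not None:
            # shift the whole fraction curve so that the 511 keV point matches
            self._pe_frac = np.clip(
                self._PE_FRAC + (pe_fraction_511 - self._PE_FRAC[-1]), 0.0, 1.0)
        self._logE = np.log(self._E)
        self._log_mu = np.log(self._MU_TOT)

    def mu_total(self, E) -> np.ndarray:
        E = np.clip(np.asarray(E, float), self._E[0], self._E[-1])
        return self.scale * np.exp(np.interp(np.log(E), self._logE, self._log_mu))

    def pe_fraction(self, E) -> np.ndarray:
        E = np.clip(np.asarray(E, float), self._E[0], self._E[-1])
        return np.interp(E, self._E, self._pe_frac)

    def mu_pe(self, E) -> np.ndarray:
        return self.mu_total(E) * self.pe_fraction(E)

    def mu_cs(self, E) -> np.ndarray:
        return self.mu_total(E) * (1.0 - self.pe_fraction(E))


@dataclass
class PhysicsConfig:
    """Toggles and parameters of the reduced-physics transport."""

    acollinearity_fwhm_deg: float = 0.25
    positron_range: bool = True
    acollinearity: bool = True
    object_attenuation: bool = True
    object_scatter: bool = True
    energy_cutoff_kev: float = 50.0
    mu_scale: float = 1.0             # multiplies the LYSO mu table (tests)
    pe_fraction_511: float | None = None
    max_chain: int = 8

    def cross_sections(self) -> LYSOCrossSections:
        return LYSOCrossSections(self.mu_scale, self.pe_fraction_511)


@dataclass
class EventBatch:
    """Struct-of-arrays record of simulated annihilation events.

    Interaction records are flat arrays indexed by an (event, photon) pair;
    ``chain_label[i, ph]`` encodes PE / CSE / CS-PE / multi-CS / miss.
    """

    annihilation_points: np.ndarray      # (n, 3) mm
    emission_times: np.ndarray           # (n,) ns
    object_scattered: np.ndarray         # (n, 2) bool
    chain_label: np.ndarray              # (n, 2) int8
    # flat interaction records
    rec_event: np.ndarray                # (m,) int64
    rec_photon: np.ndarray               # (m,) int8
    rec_order: np.ndarray                # (m,) int8
    rec_kind: np.ndarray                 # (m,) int8  (0 PE, 1 CS)
    rec_pos: np.ndarray                  # (m, 3) mm
    rec_edep: np.ndarray                 # (m,) keV
    rec_time: np.ndarray                 # (m,) ns
    rec_facet: np.ndarray                # (m,) int16

    @property
    def n_events(self) -> int:
        return self.annihilation_points.shape[0]

    def label_names(self) -> np.ndarray:
        lut = np.array([CHAIN_LABELS[i] for i in range(5)])
        return lut[self.chain_label]

    def first_interactions(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, 2, 3) first-interaction positions and (n, 2) validity mask."""
        n = self.n_events
        pos = np.full((n, 2, 3), np.nan)
        ok = np.zeros((n, 2), bool)
        first = self.rec_order == 0
        pos[self.rec_event[first], self.rec_photon[first]] = self.rec_pos[first]
        ok[self.rec_event[first], self.rec_photon[first]] = True
        return pos, ok

    def deposited_energy(self) -> np.ndarray:
        """(n, 2) total deposited energy per photon chain, keV."""
        out = np.zeros((self.n_events, 2))
        np.add.at(out, (self.rec_event, self.rec_photon.astype(np.int64)), self.rec_edep)
        return out

    def photon_records(self, event: int, photon: int):
        m = (self.rec_event == event) & (self.rec_photon == photon)
        order = np.argsort(self.rec_order[m])
        return {k: getattr(self, "rec_" + k)[m][order]
                for k in ("order", "kind", "pos", "edep", "time", "facet")}


# ---------------------------------------------------------------------------
# elementary physics


def sample_klein_nishina(E, rng, size=None):
    """Sample Compton scattering angles from the Klein-Nishina cross section.

    Returns ``(theta, E_scattered)``.  Rejection sampling in cos(theta) with
    the forward-scatter value as envelope (the differential cross section at
    511 keV and below is maximal at theta = 0).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    E = np.asarray(E, dtype=float)
    if size is not None:
        E = np.broadcast_to(E, size).copy()
    scalar = E.ndim == 0
    E = np.atleast_1d(E)
    if np.any(E <= 0):
        raise ValueError("photon energy must be > 0")
    alpha = E / 511.0
    out_cos = np.empty_like(E)
    todo = np.ones(E.shape, bool)
    # envelope: f(cos=1) = 2 (ratio=1 -> 1 + 1 - 0)
    while todo.any():
        k = int(todo.sum())
        c = rng.uniform(-1.0, 1.0, k)
        a = alpha[todo]
        ratio = 1.0 / (1.0 + a * (1.0 - c))
        f = ratio**2 * (ratio + 1.0 / ratio - (1.0 - c**2))
        acc = rng.random(k) * 2.0 <= f
        idx = np.flatnonzero(todo)
        out_cos[idx[acc]] = c[acc]
        todo[idx[acc]] = False
    theta = np.arccos(out_cos)
    E_out = E / (1.0 + alpha * (1.0 - out_cos))
    if scalar:
        return float(theta[0]), float(E_out[0])
    return theta, E_out


def path_survival(p1, p2, mu_map) -> float:
    """exp(-integral of mu dl) between two points through a voxel map."""
    from .raytrace import grid_line_integral

    p1 = np.ascontiguousarray(np.asarray(p1, float))
    p2 = np.ascontiguousarray(np.asarray(p2, float))
    integral = grid_line_integral(p1, p2, np.ascontiguousarray(mu_map.origin, dtype=float),
                                  float(mu_map.voxel_size),
                                  np.ascontiguousarray(mu_map.values, dtype=float))
    return float(np.exp(-integral))


def _rotate(d, theta, psi):
    """Rotate unit vectors ``d`` by polar angle theta about themselves."""
    d = np.atleast_2d(d)
    # orthonormal basis (e1, e2, d)
    small = np.abs(d[:, 2]) > 0.99
    a = np.where(small[:, None], np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    e1 = np.cross(a, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    st = np.sin(theta)[:, None]
    return (np.cos(theta)[:, None] * d
            + st * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2))


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


# ---------------------------------------------------------------------------
# geometry of the crystal solid


def _prism_interval(p, d, geom: ScannerGeometry):
    """[lo, hi] ray parameters inside the outer facet prism and z slab."""
    A = geom.annulus.facet_apothem
    L2 = geom.annulus.length / 2
    nd = d @ geom.normals.T          # (m, nf)
    np_ = p @ geom.normals.T
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = (A - np_) / nd
    lo = np.where(nd < 0, tt, -np.inf)
    hi = np.where(nd > 0, tt, np.inf)
    # parallel and outside -> empty
    bad = (nd == 0) & (np_ > A)
    lo = np.where(bad, np.inf, lo)
    lo = lo.max(axis=1)
    hi = hi.min(axis=1)
    dz = d[:, 2]
    pz = p[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        tz0 = (-L2 - pz) / dz
        tz1 = (L2 - pz) / dz
    zlo = np.where(dz != 0, np.minimum(tz0, tz1),
                   np.where(np.abs(pz) <= L2, -np.inf, np.inf))
    zhi = np.where(dz != 0, np.maximum(tz0, tz1),
                   np.where(np.abs(pz) <= L2, np.inf, -np.inf))
    return np.maximum(lo, zlo), np.minimum(hi, zhi)


def _bore_interval(p, d, geom: ScannerGeometry):
    r = geom.annulus.inner_radius
    px, py = p[:, 0], p[:, 1]
    dx, dy = d[:, 0], d[:, 1]
    a = dx**2 + dy**2
    b = px * dx + py * dy
    c = px**2 + py**2 - r**2
    disc = b**2 - a * c
    ok = (disc > 0) & (a > 1e-16)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(ok, (-b - sq) / a, np.inf)
        t1 = np.where(ok, (-b + sq) / a, -np.inf)
    axial = (a <= 1e-16) & (c < 0)
    t0 = np.where(axial, -np.inf, t0)
    t1 = np.where(axial, np.inf, t1)
    return t0, t1


def crystal_intervals(p, d, geom: ScannerGeometry, t_start=0.0):
    """Up to two [t0, t1] crystal segments of rays ``p + t d``, t >= t_start.

    The crystal solid is (facet prism AND z-slab) MINUS the bore cylinder, so
    a ray may traverse it in two disjoint segments (once on each side of the
    bore).  Returns ``(seg, valid)`` with ``seg`` of shape (m, 2, 2).
    """
    p = np.atleast_2d(np.asarray(p, float))
    d = np.atleast_2d(np.asarray(d, float))
    lo, hi = _prism_interval(p, d, geom)
    b0, b1 = _bore_interval(p, d, geom)
    ts = np.broadcast_to(np.asarray(t_start, float), lo.shape)
    lo = np.maximum(lo, ts)
    m = p.shape[0]
    seg = np.zeros((m, 2, 2))
    # segment 1: [lo, min(hi, b0)]
    s1a, s1b = lo, np.minimum(hi, b0)
    # segment 2: [max(lo, b1), hi]
    s2a, s2b = np.maximum(lo, b1), hi
    seg[:, 0, 0], seg[:, 0, 1] = s1a, np.maximum(s1b, s1a)
    seg[:, 1, 0], seg[:, 1, 1] = s2a, np.maximum(s2b, s2a)
    # no bore intersection in [lo, hi] -> single segment [lo, hi]
    no_bore = (b1 <= lo) | (b0 >= hi) | (b0 >= b1)
    seg[no_bore, 0, 0] = lo[no_bore]
    seg[no_bore, 0, 1] = np.maximum(hi[no_bore], lo[no_bore])
    seg[no_bore, 1] = 0.0
    valid = seg[:, :, 1] > seg[:, :, 0]
    seg[~valid] = 0.0
    return seg, valid


# ---------------------------------------------------------------------------
# transport


def _object_stage(phantom, p, d, E, t, flags, physics, rng, alive):
    """Attenuate / Compton-scatter photons in the object (analytic chords).

    Mutates ``p, d, E, t, flags, alive`` in place.
    """
    if phantom is None or not physics.object_attenuation:
        return
    active = alive.copy()
    for _ in range(3):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        t0, t1, mu = object_intervals(phantom, p[idx], d[idx])
        L = t1 - t0
        p_int = 1.0 - np.exp(-mu * L)
        u = rng.random(idx.size)
        hit = u < p_int
        if not physics.object_scatter:
            # pure attenuation: interacting photons are absorbed
            alive[idx[hit]] = False
            break
        if not hit.any():
            break
        h = idx[hit]
        s = -np.log(1.0 - u[hit] * p_int[hit]) / mu
        tt = t0[hit] + s
        p[h] = p[h] + tt[:, None] * d[h]
        t[h] = t[h] + tt / C_MM_PER_NS
        theta, E2 = sample_klein_nishina(E[h], rng)
        psi = rng.uniform(0, 2 * np.pi, h.size)
        d[h] = _rotate(d[h], theta, psi)
        E[h] = E2
        flags[h] = True
        below = E[h] < physics.energy_cutoff_kev
        alive[h[below]] = False
        active = np.zeros_like(active)
        active[h[~below]] = True


def simulate_events(phantom, geom: ScannerGeometry, physics: PhysicsConfig | None,
                    n: int, rng) -> EventBatch:
    """Simulate ``n`` annihilation events and their crystal interaction chains."""
    physics = physics or PhysicsConfig()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    xs = physics.cross_sections()

    ann, times = sample_emissions(phantom, n, rng,
                                  apply_positron_range=physics.positron_range)
    d1 = isotropic_directions(n, rng)
    d2 = -d1
    if physics.acollinearity and physics.acollinearity_fwhm_deg > 0:
        sigma = np.deg2rad(physics.acollinearity_fwhm_deg) / 2.3548
        theta = np.abs(rng.normal(0.0, sigma, n))
        psi = rng.uniform(0, 2 * np.pi, n)
        d2 = _rotate(d2, theta, psi)

    object_scattered = np.zeros((n, 2), bool)
    chain_label = np.zeros((n, 2), np.int8)
    recs = {k: [] for k in ("event", "photon", "order", "kind", "pos", "edep",
                            "time", "facet")}

    for ph, dirs in ((0, d1), (1, d2)):
        p = ann.copy()
        d = dirs.copy()
        E = np.full(n, 511.0)
        t = times.copy()
        alive = np.ones(n, bool)
        flags = np.zeros(n, bool)
        _object_stage(phantom, p, d, E, t, flags, physics, rng, alive)
        object_scattered[:, ph] = flags

        order = np.zeros(n, np.int8)
        for _step in range(physics.max_chain):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            seg, valid = crystal_intervals(p[idx], d[idx], geom, t_start=1e-9)
            len1 = np.where(valid[:, 0], seg[:, 0, 1] - seg[:, 0, 0], 0.0)
            len2 = np.where(valid[:, 1], seg[:, 1, 1] - seg[:, 1, 0], 0.0)
            mu = xs.mu_total(E[idx])
            path = rng.exponential(1.0, idx.size) / mu
            in1 = path < len1
            in2 = ~in1 & (path - len1 < len2)
            tpar = np.where(in1, seg[:, 0, 0] + path,
                            seg[:, 1, 0] + (path - len1))
            interacts = in1 | in2
            # escaped photons
            esc = idx[~interacts]
            alive[esc] = False
            hit = idx[interacts]
            if hit.size == 0:
                continue
            tp = tpar[interacts]
            p[hit] = p[hit] + tp[:, None] * d[hit]
            t[hit] = t[hit] + tp / C_MM_PER_NS
            # PE vs CS branch
            pe_frac = xs.pe_fraction(E[hit])
            is_pe = rng.random(hit.size) < pe_frac
            theta, E2 = sample_klein_nishina(E[hit], rng)
            psi = rng.uniform(0, 2 * np.pi, hit.size)
            below = (~is_pe) & (E2 < physics.energy_cutoff_kev)
            edep = np.where(is_pe, E[hit], E[hit] - E2)
            kind = np.where(is_pe, KIND_PE, KIND_CS).astype(np.int8)
            terminal = is_pe | below
            facet = np.atleast_1d(geom.locate_point(p[hit])[0])
            recs["event"].append(hit)
            recs["photon"].append(np.full(hit.size, ph, np.int8))
            recs["order"].append(order[hit].copy())
            recs["kind"].append(kind)
            recs["pos"].append(p[hit].copy())
            recs["edep"].append(edep)
            recs["time"].append(t[hit].copy())
            recs["facet"].append(facet.astype(np.int16))
            order[hit] += 1
            # sub-cutoff scattered photons are absorbed locally (mean free
            # path at 50 keV << 1 mm): terminating photoelectric record at
            # the scatter site, which keeps per-chain energy exact
            if below.any():
                b = hit[below]
                recs["event"].append(b)
                recs["photon"].append(np.full(b.size, ph, np.int8))
                recs["order"].append(order[b].copy())
                recs["kind"].append(np.full(b.size, KIND_PE, np.int8))
                recs["pos"].append(p[b].copy())
                recs["edep"].append(E2[below])
                recs["time"].append(t[b].copy())
                recs["facet"].append(facet[below].astype(np.int16))
                order[b] += 1
            alive[hit[terminal]] = False
            cont = hit[~terminal]
            E[cont] = E2[~terminal]
            d[cont] = _rotate(d[cont], theta[~terminal], psi[~terminal])

    flat = {}
    for k in recs:
        if recs[k]:
            flat[k] = np.concatenate(recs[k])
        else:
            shape = (0, 3) if k == "pos" else (0,)
            flat[k] = np.zeros(shape)

    batch = EventBatch(
        annihilation_points=ann,
        emission_times=times,
        object_scattered=object_scattered,
        chain_label=chain_label,
        rec_event=flat["event"].astype(np.int64),
        rec_photon=flat["photon"].astype(np.int8),
        rec_order=flat["order"].astype(np.int8),
        rec_kind=flat["kind"].astype(np.int8),
        rec_pos=flat["pos"].astype(float).reshape(-1, 3),
        rec_edep=flat["edep"].astype(float),
        rec_time=flat["time"].astype(float),
        rec_facet=flat["facet"].astype(np.int16) if flat["facet"].size else
        np.zeros(0, np.int16),
    )
    _assign_labels(batch)
    return batch


def _assign_labels(batch: EventBatch) -> None:
    """Derive the per-photon chain label from its interaction records."""
    n = batch.n_events
    n_rec = np.zeros((n, 2), np.int32)
    n_cs = np.zeros((n, 2), np.int32)
    pe_end = np.zeros((n, 2), bool)
    key = (batch.rec_event, batch.rec_photon.astype(np.int64))
    np.add.at(n_rec, key, 1)
    np.add.at(n_cs, key, (batch.rec_kind == KIND_CS).astype(np.int32))
    is_pe = batch.rec_kind == KIND_PE
    pe_end[batch.rec_event[is_pe], batch.rec_photon[is_pe].astype(np.int64)] = True

    lab = np.full((n, 2), LABEL_MISS, np.int8)
    lab[(n_rec >= 1) & (n_cs == 0)] = LABEL_PE
    lab[(n_cs >= 1) & ~pe_end] = LABEL_CSE
    lab[(n_cs == 1) & pe_end] = LABEL_CSPE
    lab[n_cs >= 2] = LABEL_MULTI
    batch.chain_label[:] = lab
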