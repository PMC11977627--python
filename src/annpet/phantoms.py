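"""NU4-2008 sources and phantoms: emission sampling, decay, attenuation maps.

Four source/phantom kinds are modelled:

* a Na-22 (or F-18) point source encapsulated in a 1 cm acrylic cube,
* the NU4 mouse-like count-rate phantom (25 mm x 70 mm polyethylene cylinder
  with a 3.2 mm line-source hole at 10 mm radial offset),
* the NU4 image-quality phantom (uniform chamber, five hot rods of 1-5 mm
  diameter, two cold chambers),
* a generic uniform activity cylinder.

Linear attenuation coefficients at 511 keV default to water 0.0096/mm,
polyethylene 0.0093/mm, acrylic 0.0112/mm (literature values; all
config-overridable).  Internal phantom dimensions not restated by the scanner
description follow the NU4-2008 standard and are likewise overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MU_511",
    "DecayModel",
    "NUCLIDES",
    "PointSourceSpec",
    "MousePhantomSpec",
    "IQPhantomSpec",
    "CylinderPhantomSpec",
    "MuMap",
    "activity_at",
    "sample_emissions",
    "make_attenuation_map",
]

#: default linear attenuation coefficients at 511 keV, /mm
MU_511 = {"air": 0.0, "water": 0.0096, "polyethylene": 0.0093, "acrylic": 0.0112}


@dataclass(frozen=True)
class DecayModel:
    """Half-life and positron branching fraction of a nuclide."""

    name: str
    half_life_s: float
    positron_branching: float

    def __post_init__(self):
        if not 0.0 < self.positron_branching <= 1.0:
            raise ValueError("positron branching must be in (0, 1]")


NUCLIDES = {
    "F18": DecayModel("F18", 109.77 * 60.0, 0.9686),
    "Na22": DecayModel("Na22", 2.60 * 365.25 * 86400.0, 0.9060),
}

#: positron-range FWHM in water-equivalent media, mm (isotropic Gaussian model)
POSITRON_RANGE_FWHM = {"F18": 0.54, "Na22": 1.0}


def activity_at(spec, t: float) -> float:
    """Decayed activity A0 * 2^(-t / T_half) at time ``t`` seconds."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    dm = NUCLIDES[spec.nuclide]
    return spec.activity_bq * 2.0 ** (-t / dm.half_life_s)


# ---------------------------------------------------------------------------
# phantom specifications


@dataclass(frozen=True)
class PointSourceSpec:
    nuclide: str = "Na22"
    activity_bq: float = 1.85e6
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    encapsulation_side: float = 10.0  # acrylic cube, mm
    kind: str = field(default="point", init=False)

    def __post_init__(self):
        if self.activity_bq < 0:
            raise ValueError("activity must be >= 0")


@dataclass(frozen=True)
class MousePhantomSpec:
    """NU4 mouse-like count-rate phantom (polyethylene)."""

    nuclide: str = "F18"
    activity_bq: float = 16e6
    diameter: float = 25.0
    length: float = 70.0
    hole_diameter: float = 3.2
    hole_offset: float = 10.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = field(default="mouse", init=False)

    def __post_init__(self):
        if self.hole_offset + self.hole_diameter / 2 > self.diameter / 2:
            raise ValueError("line source must lie fully inside the cylinder")


@dataclass(frozen=True)
class IQPhantomSpec:
    """NU4 image-quality phantom.

    The uniform chamber occupies z in [uniform_z0, uniform_z0 + uniform_len];
    the five hot rods (diameters 1..5 mm on a 7 mm pitch circle) sit below it,
    the two cold chambers (water / air) above it, all per NU4-2008.
    """

    nuclide: str = "F18"
    activity_bq: float = 2.96e6
    body_diameter: float = 33.5
    uniform_diameter: float = 30.0
    uniform_length: float = 15.0
    rod_diameters: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    rod_circle_radius: float = 7.0
    rod_length: float = 20.0
    cold_inner_diameter: float = 8.0
    cold_wall: float = 1.0
    cold_length: float = 15.0
    cold_offset: float = 7.5  # cold-chamber centres from axis
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = field(default="iq", init=False)

    def __post_init__(self):
        if tuple(sorted(self.rod_diameters)) != (1.0, 2.0, 3.0, 4.0, 5.0):
            raise ValueError("IQ rod diameters must be {1,2,3,4,5} mm")

    # axial layout (relative to center z): rods | uniform | cold
    @property
    def uniform_zrange(self) -> tuple[float, float]:
        return (-self.uniform_length / 2, self.uniform_length / 2)

    @property
    def rod_zrange(self) -> tuple[float, float]:
        return (-self.uniform_length / 2 - self.rod_length, -self.uniform_length / 2)

    @property
    def cold_zrange(self) -> tuple[float, float]:
        return (self.uniform_length / 2, self.uniform_length / 2 + self.cold_length)

    def rod_centers(self) -> np.ndarray:
        ang = 2 * np.pi * np.arange(len(self.rod_diameters)) / len(self.rod_diameters)
        return np.stack([self.rod_circle_radius * np.cos(ang),
                         self.rod_circle_radius * np.sin(ang)], axis=1)

    def cold_centers(self) -> np.ndarray:
        # water at +x, air at -x
        return np.array([[self.cold_offset, 0.0], [-self.cold_offset, 0.0]])


@dataclass(frozen=True)
class CylinderPhantomSpec:
    """Uniform activity cylinder of water."""

    nuclide: str = "F18"
    activity_bq: float = 3.7e6
    diameter: float = 25.0
    length: float = 40.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = field(default="cylinder", init=False)


# ---------------------------------------------------------------------------
# emission sampling


def _poisson_times(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Emission times (ns) of ``n`` ordered events from the decaying source.

    Times follow the inhomogeneous Poisson profile of radioactive decay: the
    cumulative intensity is Lambda(t) = A0*B/ln2*T*(1 - 2^(-t/T)); drawing
    uniform quantiles of Lambda restricted to the first ``n`` expected events
    gives times with the correct decay-weighted density.
    """
    dm = NUCLIDES[spec.nuclide]
    rate0 = spec.activity_bq * dm.positron_branching  # emissions per s at t=0
    if rate0 <= 0 or n == 0:
        return np.zeros(n)
    # duration that contains n expected events (cap at 10 half-lives)
    lam = math.log(2.0) / dm.half_life_s
    x = 1.0 - n * lam / rate0
    T = -math.log(max(x, 2.0 ** -10)) / lam
    u = np.sort(rng.random(n))
    # invert Lambda(t)/Lambda(T) = u
    denom = 1.0 - math.exp(-lam * T)
    t = -np.log(1.0 - u * denom) / lam
    return t * 1e9  # ns


def sample_emissions(spec, n: int, rng, apply_positron_range: bool = True):
    """Sample ``n`` positron annihilation sites and emission times.

    Returns ``(positions (n,3) mm, times (n,) ns)``.  Positions are uniform
    over the active region of the phantom; the positron range is modelled as
    an isotropic Gaussian blur of the emission point (toggleable).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n < 0:
        raise ValueError("n must be >= 0")
    k = getattr(spec, "kind", None)
    c = np.asarray(getattr(spec, "position", getattr(spec, "center", (0, 0, 0))), float)

    if k == "point":
        pos = np.tile(c, (n, 1))
    elif k == "mouse":
        r = spec.hole_diameter / 2 * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        pos = np.stack(
            [spec.hole_offset + r * np.cos(th), r * np.sin(th),
             spec.length * (rng.random(n) - 0.5)], axis=1) + c
    elif k == "cylinder":
        r = spec.diameter / 2 * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        pos = np.stack([r * np.cos(th), r * np.sin(th),
                        spec.length * (rng.random(n) - 0.5)], axis=1) + c
    elif k == "iq":
        pos = _sample_iq(spec, n, rng) + c
    else:
        raise ValueError(f"unknown phantom kind: {k!r}")

    if apply_positron_range and n > 0:
        fwhm = POSITRON_RANGE_FWHM.get(spec.nuclide, 0.5)
        pos = pos + rng.normal(0.0, fwhm / 2.3548, size=(n, 3))

    times = _poisson_times(spec, n, rng)
    return pos, times


def _sample_iq(spec: IQPhantomSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    # activity split between uniform chamber and rods by volume
    v_uni = math.pi * (spec.uniform_diameter / 2) ** 2 * spec.uniform_length
    v_rods = sum(math.pi * (d / 2) ** 2 * spec.rod_length for d in spec.rod_diameters)
    p_uni = v_uni / (v_uni + v_rods)
    in_uni = rng.random(n) < p_uni
    pos = np.empty((n, 3))
    m = int(in_uni.sum())
    r = spec.uniform_diameter / 2 * np.sqrt(rng.random(m))
    th = 2 * np.pi * rng.random(m)
    z0, z1 = spec.uniform_zrange
    pos[in_uni] = np.stack([r * np.cos(th), r * np.sin(th),
                            z0 + (z1 - z0) * rng.random(m)], axis=1)
    k = n - m
    if k:
        diam = np.asarray(spec.rod_diameters)
        w = diam**2 / (diam**2).sum()
        rod = rng.choice(len(diam), size=k, p=w)
        centers = spec.rod_centers()[rod]
        rr = diam[rod] / 2 * np.sqrt(rng.random(k))
        tt = 2 * np.pi * rng.random(k)
        z0, z1 = spec.rod_zrange
        pos[~in_uni] = np.stack(
            [centers[:, 0] + rr * np.cos(tt), centers[:, 1] + rr * np.sin(tt),
             z0 + (z1 - z0) * rng.random(k)], axis=1)
    return pos


# ---------------------------------------------------------------------------
# attenuation maps


@dataclass
class MuMap:
    """Voxelized linear attenuation coefficients (/mm) on a world-aligned grid."""

    values: np.ndarray       # (nx, ny, nz), float32
    voxel_size: float        # mm, isotropic
    origin: np.ndarray       # world position of the corner of voxel (0,0,0)

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers(self):
        n = self.values.shape
        ax = [self.origin[i] + (np.arange(n[i]) + 0.5) * self.voxel_size for i in range(3)]
        return ax

    def save(self, path_prefix: str) -> None:
        """Write raw float32 + JSON sidecar (dimensions, voxel size, origin)."""
        import json

        self.values.astype("<f4").tofile(path_prefix + ".f32")
        with open(path_prefix + ".json", "w") as fh:
            json.dump({"shape": list(self.values.shape),
                       "voxel_size_mm": self.voxel_size,
                       "origin_mm": [float(x) for x in self.origin],
                       "dtype": "<f4", "order": "C"}, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "MuMap":
        import json

        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        vals = np.fromfile(path_prefix + ".f32", dtype="<f4").reshape(meta["shape"])
        return cls(vals, meta["voxel_size_mm"], np.asarray(meta["origin_mm"]))


def make_attenuation_map(
    spec,
    voxel_size: float = 1.0,
    extent: float | None = None,
    mu: dict | None = None,
) -> MuMap:
    """Voxelize the 511 keV attenuation map of a phantom, world-aligned.

    ``extent`` is the half-width of the cubic-footprint grid in x and y (the
    z extent adapts to the phantom length); defaults cover the object.
    """
    mu = {**MU_511, **(mu or {})}
    k = getattr(spec, "kind", None)
    c = np.asarray(getattr(spec, "position", getattr(spec, "center", (0, 0, 0))), float)

    if k == "point":
        half_xy = extent or (spec.encapsulation_side / 2 + 2)
        half_z = spec.encapsulation_side / 2 + 2
    elif k in ("mouse", "cylinder"):
        half_xy = extent or (spec.diameter / 2 + 2)
        half_z = spec.length / 2 + 2
    elif k == "iq":
        half_xy = extent or (spec.body_diameter / 2 + 2)
        half_z = spec.rod_length + spec.uniform_length / 2 + spec.cold_length + 2
    else:
        raise ValueError(f"unknown phantom kind: {k!r}")

    nx = ny = max(2, int(np.ceil(2 * half_xy / voxel_size)))
    nz = max(2, int(np.ceil(2 * half_z / voxel_size)))
    origin = c - np.array([nx, ny, nz]) * voxel_size / 2
    xs = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * voxel_size
    zs = origin[2] + (np.arange(nz) + 0.5) * voxel_size
    X, Y, Z = np.meshgrid(xs - c[0], ys - c[1], zs - c[2], indexing="ij")
    R2 = X**2 + Y**2
    vals = np.zeros((nx, ny, nz), dtype=np.float32)

    if k == "point":
        h = spec.encapsulation_side / 2
        cube = (np.abs(X) <= h) & (np.abs(Y) <= h) & (np.abs(Z) <= h)
        vals[cube] = mu["acrylic"]
    elif k == "mouse":
        body = (R2 <= (spec.diameter / 2) ** 2) & (np.abs(Z) <= spec.length / 2)
        vals[body] = mu["polyethylene"]
        hole = ((X - spec.hole_offset) ** 2 + Y**2 <= (spec.hole_diameter / 2) ** 2) & body
        vals[hole] = mu["water"]  # water-equivalent activity solution
    elif k == "cylinder":
        body = (R2 <= (spec.diameter / 2) ** 2) & (np.abs(Z) <= spec.length / 2)
        vals[body] = mu["water"]
    elif k == "iq":
        zr0, zr1 = spec.rod_zrange
        zu0, zu1 = spec.uniform_zrange
        zc0, zc1 = spec.cold_zrange
        body = (R2 <= (spec.body_diameter / 2) ** 2) & (Z >= zr0) & (Z <= zc1)
        vals[body] = mu["water"]
        # rod section: acrylic body with water-filled rods
        rod_sec = body & (Z < zu0)
        vals[rod_sec] = mu["acrylic"]
        for d, (cx, cy) in zip(spec.rod_diameters, spec.rod_centers()):
            rod = ((X - cx) ** 2 + (Y - cy) ** 2 <= (d / 2) ** 2) & rod_sec
            vals[rod] = mu["water"]
        # cold chambers: thin acrylic wall, water / air fill
        cold = (Z > zu1) & body
        for (cx, cy), fill in zip(spec.cold_centers(), ("water", "air")):
            rr2 = (X - cx) ** 2 + (Y - cy) ** 2
            rin = spec.cold_inner_diameter / 2
            wall = (rr2 <= (rin + spec.cold_wall) ** 2) & cold
            vals[wall] = mu["acrylic"]
            inner = (rr2 <= rin**2) & cold
            vals[inner] = mu[fill]
    return MuMap(vals, voxel_size, origin)


# ---------------------------------------------------------------------------
# analytic object chords (used by the photon transport for speed)


def object_intervals(spec, p: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Entry/exit ray parameters of the phantom body and its bulk mu.

    Returns ``(t0, t1, mu_bulk)`` for rays ``p + t d`` (t >= 0); empty
    intersections give t0 = t1 = 0.  The body is approximated by its dominant
    material for transport; recon-side corrections use the full voxel map.
    """
    k = getattr(spec, "kind", None)
    c = np.asarray(getattr(spec, "position", getattr(spec, "center", (0, 0, 0))), float)
    if k == "point":
        h = spec.encapsulation_side / 2
        t0, t1 = _box_interval(p - c, d, h)
        return t0, t1, MU_511["acrylic"]
    if k == "mouse":
        t0, t1 = _cyl_interval(p - c, d, spec.diameter / 2, spec.length / 2)
        return t0, t1, MU_511["polyethylene"]
    if k == "cylinder":
        t0, t1 = _cyl_interval(p - c, d, spec.diameter / 2, spec.length / 2)
        return t0, t1, MU_511["water"]
    if k == "iq":
        zr0, _ = spec.rod_zrange
        _, zc1 = spec.cold_zrange
        half = (zc1 - zr0) / 2
        mid = np.array([0.0, 0.0, (zc1 + zr0) / 2])
        t0, t1 = _cyl_interval(p - c - mid, d, spec.body_diameter / 2, half)
        return t0, t1, MU_511["water"]
    raise ValueError(f"unknown phantom kind: {k!r}")


def _cyl_interval(p, d, radius, half_len):
    """Clipped [t0, t1] of rays with a z-aligned cylinder, t >= 0."""
    px, py, pz = p[:, 0], p[:, 1], p[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    a = dx**2 + dy**2
    b = px * dx + py * dy
    cq = px**2 + py**2 - radius**2
    disc = b**2 - a * cq
    ok = (disc > 0) & (a > 1e-16)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tr0 = np.where(ok, (-b - sq) / a, np.inf)
        tr1 = np.where(ok, (-b + sq) / a, -np.inf)
        # axial rays inside the radius
        axial = (a <= 1e-16) & (cq <= 0)
        tr0 = np.where(axial, -np.inf, tr0)
        tr1 = np.where(axial, np.inf, tr1)
        tz0 = np.where(dz != 0, (-half_len - pz) / dz, np.where(np.abs(pz) <= half_len, -np.inf, np.inf))
        tz1 = np.where(dz != 0, (half_len - pz) / dz, np.where(np.abs(pz) <= half_len, np.inf, -np.inf))
        lo = np.minimum(tz0, tz1)
        hi = np.maximum(tz0, tz1)
    t0 = np.maximum(np.maximum(tr0, lo), 0.0)
    t1 = np.maximum(np.minimum(tr1, hi), 0.0)
    bad = t1 <= t0
    t0 = np.where(bad, 0.0, t0)
    t1 = np.where(bad, 0.0, t1)
    return t0, t1


def _box_interval(p, d, half):
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (-half - p) / d
        t_hi = (half - p) / d
        inside = np.abs(p) <= half
        t_lo = np.where(d == 0, np.where(inside, -np.inf, np.inf), t_lo)
        t_hi = np.where(d == 0, np.where(inside, np.inf, -np.inf), t_hi)
    lo = np.minimum(t_lo, t_hi).max(axis=1)
    hi = np.maximum(t_lo, t_hi).min(axis=1)
    t0 = np.maximum(lo, 0.0)
    t1 = np.maximum(hi, 0.0)
    bad = t1 <= t0
    return np.where(bad, 0.0, t0), np.where(bad, 0.0, t1)
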