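"""Seeded synthetic protocol fixtures mirroring the NU4 measurement plans.

Each fixture reproduces the structure of one performance protocol at a
configurable (desk) scale:

* ``resolution``: Na-22 point source at 5/10/15/18 mm radial offsets, at the
  axial centre and at one quarter of the axial FOV;
* ``sensitivity``: the point source at fifteen axial positions 5 mm apart;
* ``countrate``: the mouse-like phantom through a decaying-activity sweep
  (default eighteen acquisitions spanning ten hours of F-18 decay);
* ``iq``: one image-quality phantom acquisition;
* ``training``: a photoelectric positioning set (features + labels).
"""

from __future__ import annotations

import numpy as np

from .config import stage_rng
from .geometry import ScannerGeometry
from .optics import OpticalModel
from .phantoms import MousePhantomSpec, IQPhantomSpec, PointSourceSpec, activity_at
from .positioning import make_pe_dataset

__all__ = ["make_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("resolution", "sensitivity", "countrate", "iq", "training")


def make_fixtures(kind: str, size: int, seed: int,
                  geom: ScannerGeometry | None = None) -> dict:
    """Build the in-memory fixture for one protocol.

    ``size`` scales the per-acquisition event count; ``size = 0`` yields the
    protocol structure with empty acquisitions.
    """
    geom = geom or ScannerGeometry()
    rng = stage_rng(seed, "fixtures")
    if kind == "resolution":
        offsets = (5.0, 10.0, 15.0, 18.0)
        planes = (0.0, geom.annulus.length / 4.0)
        acqs = [{"source": PointSourceSpec(position=(r, 0.0, z)),
                 "radial_offset": r, "axial_plane": z, "n_events": size}
                for z in planes for r in offsets]
        return {"kind": kind, "acquisitions": acqs, "seed": seed}
    if kind == "sensitivity":
        zs = 5.0 * (np.arange(15) - 7)
        acqs = [{"source": PointSourceSpec(position=(0.0, 0.0, float(z))),
                 "axial_position": float(z), "n_events": size} for z in zs]
        return {"kind": kind, "acquisitions": acqs, "seed": seed}
    if kind == "countrate":
        phantom = MousePhantomSpec()
        t_hours = np.linspace(0.0, 10.0, 18)
        acqs = [{"time_h": float(t),
                 "activity_bq": activity_at(phantom, t * 3600.0),
                 "n_events": size} for t in t_hours]
        return {"kind": kind, "phantom": phantom, "acquisitions": acqs,
                "seed": seed}
    if kind == "iq":
        return {"kind": kind, "phantom": IQPhantomSpec(),
                "acquisitions": [{"n_events": size}], "seed": seed}
    if kind == "training":
        if size == 0:
            return {"kind": kind, "features": np.zeros((0, 192)),
                    "local": np.zeros((0, 3)), "seed": seed}
        ds = make_pe_dataset(geom, OpticalModel(), size, rng)
        ds["kind"] = kind
        ds["seed"] = seed
        return ds
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"known kinds: {FIXTURE_KINDS}")
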