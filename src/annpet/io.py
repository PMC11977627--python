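"""List-mode and image file formats.

Binary containers are little-endian fixed-length records preceded by a
length-prefixed JSON header (schema name/version, geometry hash, seed,
record count, numpy dtype descriptor).  Round trips are bit-exact;
truncated payloads raise with the failing record index, and a geometry-hash
mismatch against a supplied geometry raises unless explicitly overridden.
"""

from __future__ import annotations

import json
import struct

import numpy as np

from .daq import CoincidenceBatch
from .recon import ProjectedLORs, SinogramSpec, SSRBSinogram

__all__ = [
    "ListModeError",
    "write_coincidences", "read_coincidences",
    "write_lors", "read_lors",
    "write_sinogram", "read_sinogram",
]

MAGIC = b"ANNPET1\n"

COINC_DTYPE = np.dtype([
    ("time", "<i8"),
    ("primary", "u1"), ("secondary", "u1"),
    ("dist", "<f4", (2, 12, 16)),
    ("truth_event", "<i8", (2,)),
    ("truth_photon", "i1", (2,)),
])

LOR_DTYPE = np.dtype([
    ("plane", "u1", (2,)),
    ("it", "<i2", (2,)),
    ("ia", "<i2", (2,)),
    ("weight", "<f4"),
    ("time", "<i8"),
])


class ListModeError(IOError):
    pass


def _write(path, schema: str, records: np.ndarray, meta: dict) -> None:
    header = {"schema": schema, "version": 1, "count": int(records.size),
              "dtype": records.dtype.descr, **meta}
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<q", len(blob)))
        fh.write(blob)
        fh.write(records.tobytes())


def _read(path, schema: str):
    with open(path, "rb") as fh:
        if fh.read(len(MAGIC)) != MAGIC:
            raise ListModeError(f"{path}: bad magic, not an annpet container")
        (hlen,) = struct.unpack("<q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        if header.get("schema") != schema:
            raise ListModeError(
                f"{path}: schema {header.get('schema')!r}, expected {schema!r}")
        dtype = np.dtype([tuple(d) if len(d) == 2 else (d[0], d[1], tuple(d[2]))
                          for d in header["dtype"]])
        payload = fh.read()
    n = header["count"]
    if len(payload) != n * dtype.itemsize:
        got = len(payload) // dtype.itemsize
        raise ListModeError(
            f"{path}: truncated at record {got} of {n}")
    return header, np.frombuffer(payload, dtype=dtype)


def _check_geometry(header, geom, allow_mismatch):
    if geom is not None and header.get("geometry_hash") not in (None, geom.config_hash()):
        if not allow_mismatch:
            raise ListModeError(
                "geometry hash mismatch: file "
                f"{header.get('geometry_hash')} vs supplied {geom.config_hash()} "
                "(pass allow_geometry_mismatch=True to override)")


def write_coincidences(path, coinc: CoincidenceBatch, geom=None,
                       seed=None) -> None:
    rec = np.zeros(coinc.n, COINC_DTYPE)
    rec["time"] = np.round(coinc.times).astype(np.int64)
    rec["primary"] = coinc.primary
    rec["secondary"] = coinc.secondary
    rec["dist"] = coinc.dists
    rec["truth_event"] = coinc.truth_event
    rec["truth_photon"] = coinc.truth_photon
    meta = {"seed": seed}
    if geom is not None:
        meta["geometry_hash"] = geom.config_hash()
    if coinc.singles_counts is not None:
        meta["singles_counts"] = [int(x) for x in coinc.singles_counts]
    meta["n_multiple_discarded"] = coinc.n_multiple_discarded
    _write(path, "coincidences", rec, meta)


def read_coincidences(path, geom=None, allow_geometry_mismatch=False):
    header, rec = _read(path, "coincidences")
    _check_geometry(header, geom, allow_geometry_mismatch)
    coinc = CoincidenceBatch(
        times=rec["time"].astype(float),
        primary=rec["primary"].astype(int),
        secondary=rec["secondary"].astype(int),
        dists=rec["dist"].copy(),
        truth_event=rec["truth_event"].copy(),
        truth_photon=rec["truth_photon"].copy(),
        singles_counts=np.asarray(header.get("singles_counts", []))
        if header.get("singles_counts") else None,
        n_multiple_discarded=header.get("n_multiple_discarded", 0),
    )
    return coinc, header


def write_lors(path, lors: ProjectedLORs, geom=None, seed=None) -> None:
    rec = np.zeros(lors.n, LOR_DTYPE)
    rec["plane"] = lors.plane
    rec["it"] = lors.it
    rec["ia"] = lors.ia
    rec["weight"] = lors.weight
    rec["time"] = np.round(lors.times).astype(np.int64)
    meta = {"seed": seed}
    if geom is not None:
        meta["geometry_hash"] = geom.config_hash()
    _write(path, "projected_lors", rec, meta)


def read_lors(path, geom=None, allow_geometry_mismatch=False):
    header, rec = _read(path, "projected_lors")
    _check_geometry(header, geom, allow_geometry_mismatch)
    lors = ProjectedLORs(
        plane=rec["plane"].astype(np.uint8),
        it=rec["it"].astype(np.int16),
        ia=rec["ia"].astype(np.int16),
        weight=rec["weight"].astype(float),
        times=rec["time"].astype(float),
    )
    return lors, header


def write_sinogram(path_prefix: str, sino: SSRBSinogram) -> None:
    sino.counts.astype("<f4").tofile(path_prefix + ".f32")
    with open(path_prefix + ".json", "w") as fh:
        json.dump({"shape": list(sino.counts.shape),
                   "n_angles": sino.spec.n_angles, "r_bin": sino.spec.r_bin,
                   "r_max": sino.spec.r_max,
                   "max_ring_difference": sino.spec.max_ring_difference,
                   "slice_pitch": sino.slice_pitch, "z0": sino.z0,
                   "n_rejected": sino.n_rejected, "dtype": "<f4"}, fh)


def read_sinogram(path_prefix: str) -> SSRBSinogram:
    with open(path_prefix + ".json") as fh:
        meta = json.load(fh)
    counts = np.fromfile(path_prefix + ".f32", dtype="<f4").reshape(meta["shape"])
    spec = SinogramSpec(n_angles=meta["n_angles"], r_bin=meta["r_bin"],
                        r_max=meta["r_max"],
                        max_ring_difference=meta["max_ring_difference"])
    return SSRBSinogram(counts.astype(float), spec, meta["slice_pitch"],
                        meta["z0"], meta["n_rejected"])
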