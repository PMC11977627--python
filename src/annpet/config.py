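"""Run configuration and deterministic seeding.

One master seed fully determines every stochastic output: each pipeline
stage draws from ``numpy.random.SeedSequence(master_seed, spawn_key=(k,))``
where ``k`` is the stage's fixed index in ``STAGE_INDEX`` — stages are
therefore independently reproducible.  Configurations load from / dump to
YAML with nested sections mirroring the module structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .daq import DAQConfig
from .gamma_mc import PhysicsConfig
from .geometry import AnnulusSpec, ScannerGeometry, SensorGrid, VirtualDetectorSpec
from .optics import NoiseConfig, OpticalModel
from .positioning import HarmonizationParams
from . import phantoms as _ph

__all__ = ["RunConfig", "STAGE_INDEX", "stage_rng", "stage_seed", "load_config"]

STAGE_INDEX = {"simulate": 0, "daq": 1, "position": 2, "train": 3,
               "project": 4, "reconstruct": 5, "analyze": 6, "fixtures": 7}

PHANTOM_KINDS = {"point": _ph.PointSourceSpec, "mouse": _ph.MousePhantomSpec,
                 "iq": _ph.IQPhantomSpec, "cylinder": _ph.CylinderPhantomSpec}


def stage_seed(master_seed: int, stage: str) -> int:
    """31-bit child seed for a named pipeline stage."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(STAGE_INDEX[stage],)))


@dataclass
class ReconConfig:
    method: str = "mlem"          # or "fbp"
    n_iter: int = 10
    voxel_size: float = 0.5       # desk-scale default; hardware uses 0.25
    grid_shape: tuple = (64, 64, 32)
    attenuation_correction: bool = True
    randoms_correction: bool = True
    sens_stride: tuple = (2, 4)


@dataclass
class RunConfig:
    master_seed: int = 1
    n_events: int = 50_000
    phantom_kind: str = "point"
    phantom_args: dict = field(default_factory=dict)
    annulus: AnnulusSpec = field(default_factory=AnnulusSpec)
    sensors: SensorGrid = field(default_factory=SensorGrid)
    virtual: VirtualDetectorSpec = field(default_factory=VirtualDetectorSpec)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    optics: OpticalModel = field(default_factory=OpticalModel)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    daq: DAQConfig = field(default_factory=DAQConfig)
    harmonization: HarmonizationParams = field(default_factory=HarmonizationParams)
    positioning_method: str = "com"    # "com" | "nn" | "truth"
    recon: ReconConfig = field(default_factory=ReconConfig)
    stages: tuple = ("simulate", "daq", "position", "project", "reconstruct")

    def geometry(self) -> ScannerGeometry:
        return ScannerGeometry(self.annulus, self.sensors, self.virtual)

    def phantom(self):
        return PHANTOM_KINDS[self.phantom_kind](**self.phantom_args)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stages",):
            d[k] = list(d[k])
        d["recon"]["grid_shape"] = list(d["recon"]["grid_shape"])
        d["recon"]["sens_stride"] = list(d["recon"]["sens_stride"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "annulus": AnnulusSpec, "sensors": SensorGrid,
            "virtual": VirtualDetectorSpec, "physics": PhysicsConfig,
            "optics": OpticalModel, "noise": NoiseConfig, "daq": DAQConfig,
            "harmonization": HarmonizationParams,
        }
        kwargs = {}
        for k, v in d.items():
            if k in sub and isinstance(v, dict):
                kwargs[k] = sub[k](**v)
            elif k == "recon" and isinstance(v, dict):
                v = dict(v)
                if "grid_shape" in v:
                    v["grid_shape"] = tuple(v["grid_shape"])
                if "sens_stride" in v:
                    v["sens_stride"] = tuple(v["sens_stride"])
                kwargs[k] = ReconConfig(**v)
            elif k == "stages":
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        # drop the init=False phantom 'kind' fields if present
        pa = kwargs.get("phantom_args")
        if isinstance(pa, dict):
            pa.pop("kind", None)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)
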