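"""End-to-end orchestration: simulate -> daq -> position -> project ->
reconstruct (-> analyze), with a manifest of hashed outputs.

Any contiguous sub-chain of stages can be run; outputs are written to the
run directory and listed in the manifest with SHA-256 hashes, so a repeated
run at the same configuration and master seed reproduces the manifest
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import os
import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import io as lmio
from .config import RunConfig, stage_rng
from .daq import classify_prompts, find_coincidences, make_singles
from .gamma_mc import simulate_events
from .phantoms import make_attenuation_map
from .positioning import (DepthLUT, com_position, harmonize, make_pe_dataset,
                          predict_position)
from .recon import (ImageGrid, attenuation_weights, estimate_randoms,
                    fbp_volume, mlem_reconstruct, project_lors, ssrb_rebin)

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stages_run: list = field(default_factory=list)
    files: dict = field(default_factory=dict)        # name -> sha256
    counts: dict = field(default_factory=dict)       # stage -> events in/out
    wall_clock_s: dict = field(default_factory=dict)  # informational

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash,
                       "master_seed": self.master_seed,
                       "stages_run": self.stages_run, "files": self.files,
                       "counts": self.counts,
                       "wall_clock_s": self.wall_clock_s}, fh, indent=2)

    def reproducibility_key(self) -> dict:
        """The deterministic part of the manifest (no wall clock)."""
        return {"config_hash": self.config_hash, "files": self.files,
                "counts": self.counts}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str) -> RunManifest:
    """Execute the configured stage chain; returns the run manifest."""
    os.makedirs(outdir, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
                           config.master_seed)
    geom = config.geometry()
    phantom = config.phantom()
    state: dict = {}

    def record(name, path):
        manifest.files[name] = _sha256(path)

    for stage in config.stages:
        t0 = _time.time()
        try:
            if stage == "simulate":
                rng = stage_rng(config.master_seed, "simulate")
                state["batch"] = simulate_events(phantom, geom, config.physics,
                                                 config.n_events, rng)
                manifest.counts["simulate"] = {"events": config.n_events}

            elif stage == "daq":
                rng = stage_rng(config.master_seed, "daq")
                singles = make_singles(state["batch"], config.optics, geom,
                                       config.daq, config.noise, rng)
                coinc = find_coincidences(singles, config.daq, geom)
                state["singles"] = singles
                state["coinc"] = coinc
                state["prompt_split"] = classify_prompts(coinc, state["batch"])
                path = os.path.join(outdir, "coincidences.lm")
                lmio.write_coincidences(path, coinc, geom, config.master_seed)
                record("coincidences.lm", path)
                manifest.counts["daq"] = {
                    "singles": int(singles.n), "prompts": int(coinc.n),
                    "trues": state["prompt_split"]["trues"],
                    "scatters": state["prompt_split"]["scatters"],
                    "randoms": state["prompt_split"]["randoms"],
                    "multiple_discarded": int(coinc.n_multiple_discarded)}

            elif stage == "position":
                coinc = state["coinc"]
                rng = stage_rng(config.master_seed, "position")
                h1, z1 = harmonize(coinc.dists[:, 0], config.harmonization)
                h2, z2 = harmonize(coinc.dists[:, 1], config.harmonization)
                good = ~(z1 | z2)
                if config.positioning_method == "truth":
                    pos_first, ok = state["batch"].first_interactions()
                    ev = coinc.truth_event
                    ph = coinc.truth_photon
                    good &= (ev >= 0).all(axis=1)
                    good &= ok[np.maximum(ev[:, 0], 0), ph[:, 0]]
                    good &= ok[np.maximum(ev[:, 1], 0), ph[:, 1]]
                    e1 = pos_first[ev[good, 0], ph[good, 0]]
                    e2 = pos_first[ev[good, 1], ph[good, 1]]
                elif config.positioning_method == "nn":
                    model = state.get("positioner")
                    if model is None:
                        from .nn import NetConfig
                        from .positioning import train_positioner

                        ds = make_pe_dataset(geom, config.optics, 20_000, rng)
                        model = train_positioner(ds, NetConfig(epochs=6),
                                                 seed=config.master_seed)
                        state["positioner"] = model
                    e1, _ = predict_position(model, h1[good], coinc.primary[good], geom)
                    e2, _ = predict_position(model, h2[good], coinc.secondary[good], geom)
                else:  # centre-of-mass baseline
                    lut = state.get("depth_lut")
                    if lut is None:
                        ds = make_pe_dataset(geom, config.optics, 4000, rng)
                        lut = DepthLUT.fit(ds["m2"], ds["local"][:, 1])
                        state["depth_lut"] = lut
                    e1, _ = com_position(h1[good], coinc.primary[good], geom, lut)
                    e2, _ = com_position(h2[good], coinc.secondary[good], geom, lut)
                state["estimates"] = (e1, e2, good)
                manifest.counts["position"] = {"in": int(coinc.n),
                                               "out": int(good.sum())}

            elif stage == "project":
                e1, e2, good = state["estimates"]
                coinc = state["coinc"]
                lors, acc, _ = project_lors(
                    e1, e2, coinc.primary[good], coinc.secondary[good], geom,
                    times=coinc.times[good])
                if config.recon.attenuation_correction:
                    mu = state.get("mu_map")
                    if mu is None:
                        mu = make_attenuation_map(phantom)
                        state["mu_map"] = mu
                    attenuation_weights(lors, mu, geom)
                state["lors"] = lors
                path = os.path.join(outdir, "lors.lm")
                lmio.write_lors(path, lors, geom, config.master_seed)
                record("lors.lm", path)
                manifest.counts["project"] = {"in": int(len(acc)),
                                              "out": int(lors.n)}

            elif stage == "reconstruct":
                lors = state["lors"]
                rcfg = config.recon
                if rcfg.method == "fbp":
                    sino = ssrb_rebin(lors, geom)
                    vol = fbp_volume(sino, voxel=rcfg.voxel_size)
                    state["sinogram"] = sino
                else:
                    grid = ImageGrid(rcfg.voxel_size, tuple(rcfg.grid_shape))
                    r_per_lor = 0.0
                    if rcfg.randoms_correction and state.get("singles") is not None:
                        sing = state["singles"]
                        span = max((sing.times.max() - sing.times.min()) / 1e9, 1e-9)
                        rates = sing.facet_counts(geom.n_facets) / span
                        rest = estimate_randoms(rates,
                                                config.daq.coincidence_window_ns,
                                                geom)
                        n_prompt = max(state["coinc"].n, 1)
                        r_per_lor = rest["total_rate"] * span / n_prompt
                    vol, ll = mlem_reconstruct(
                        lors, geom, grid, n_iter=rcfg.n_iter,
                        mu_map=None if not rcfg.attenuation_correction
                        else state.get("mu_map"),
                        randoms_per_lor=r_per_lor,
                        sens_stride=tuple(rcfg.sens_stride))
                    state["loglik"] = ll
                state["volume"] = vol
                path = os.path.join(outdir, "volume")
                vol.save(path)
                record("volume.f32", path + ".f32")
                record("volume.json", path + ".json")
                manifest.counts["reconstruct"] = {"lors": int(lors.n)}

            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest.to_json(os.path.join(outdir, "manifest.partial.json"))
            raise PipelineError(stage, exc) from exc
        manifest.stages_run.append(stage)
        manifest.wall_clock_s[stage] = round(_time.time() - t0, 3)

    manifest.to_json(os.path.join(outdir, "manifest.json"))
    state["manifest"] = manifest
    run_pipeline.last_state = state  # inspection hook for library callers
    return manifest
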