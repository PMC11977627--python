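"""Trigger and coincidence logic.

The hardware sums each MPPC array's sixteen channels, applies a 125 mV
threshold to those sums to suppress electronic noise (represented here by a
threshold in photoelectron units), groups surviving array sums into
fourteen per-facet sums (no energy threshold on those), and searches for
two partner facets firing within a 2 ns coincidence window.  The window is
the FULL width of the accepted time-difference range (|dt| <= window/2),
the convention under which the singles-product randoms estimate
R = window * S_i * S_j agrees with a delayed-window measurement.  Groups
of three or more in-window singles are discarded.

Each accepted coincidence carries two 12 x 16 photon distributions: for the
primary facet (largest facet sum) and the secondary (largest among the
primary's seven partners), each concatenating the 4 x 16 pixel grids of
(facet-1, facet, facet+1) in increasing-azimuth order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry
from .optics import (NoiseConfig, OpticalModel, chain_expected_maps,
                     make_gain_map, sample_signals)

__all__ = [
    "DAQConfig",
    "SinglesBatch",
    "CoincidenceBatch",
    "apply_thresholds",
    "make_singles",
    "find_coincidences",
    "assemble_distribution",
    "classify_prompts",
]


@dataclass(frozen=True)
class DAQConfig:
    array_threshold: float = 5.0        # p.e.; stand-in for the 125 mV analog cut
    coincidence_window_ns: float = 2.0  # FULL width of the dt acceptance
    intrinsic_singles_rate: float = 0.0  # cps per facet (Lu-176 stand-in)

    def __post_init__(self):
        if self.coincidence_window_ns <= 0:
            raise ValueError("coincidence window must be > 0")
        if self.array_threshold < 0:
            raise ValueError("array threshold must be >= 0")


def apply_thresholds(signal_map: np.ndarray, cfg: DAQConfig):
    """Array-level threshold, then facet sums.

    ``signal_map``: (..., nf, 4, 16) pixel amplitudes.  Array j of a facet
    covers axial pixel rows 4j..4j+3.  Array sums below the threshold are
    zeroed (inclusive >= keeps a sum exactly at threshold); facet sums are
    the sums of the surviving four array sums — no facet-level energy cut.

    Returns ``(array_sums, facet_sums)`` of shapes (..., nf, 4), (..., nf).
    """
    sm = np.asarray(signal_map)
    *lead, nf, nu, nax = sm.shape
    arrays = sm.reshape(*lead, nf, nu, nax // 4, 4).sum(axis=(-3, -1))
    arrays = np.where(arrays >= cfg.array_threshold, arrays, 0.0)
    return arrays, arrays.sum(axis=-1)


@dataclass
class SinglesBatch:
    """Time-ordered singles: facet id, per-array sums, 3-facet pixel maps."""

    times: np.ndarray          # (k,) ns
    facets: np.ndarray         # (k,) int
    facet_sums: np.ndarray     # (k,) p.e. (post-threshold)
    array_sums: np.ndarray     # (k, 4) surviving array sums of the facet
    maps3: np.ndarray          # (k, 3, 4, 16) raw amplitudes, facet -1/0/+1
    truth_event: np.ndarray    # (k,) int64, -1 for background singles
    truth_photon: np.ndarray   # (k,) int8

    @property
    def n(self) -> int:
        return self.times.size

    def sort_by_time(self) -> "SinglesBatch":
        o = np.argsort(self.times, kind="stable")
        return SinglesBatch(*(getattr(self, f)[o] for f in
                              ("times", "facets", "facet_sums", "array_sums",
                               "maps3", "truth_event", "truth_photon")))

    def facet_counts(self, nf: int) -> np.ndarray:
        return np.bincount(self.facets, minlength=nf)

    @classmethod
    def bare(cls, times, facets, facet_sums=None) -> "SinglesBatch":
        """Map-less singles timeline (rate and randoms studies)."""
        times = np.asarray(times, float)
        facets = np.asarray(facets, int)
        k = times.size
        if facet_sums is None:
            facet_sums = np.ones(k)
        return cls(times, facets, np.asarray(facet_sums, float),
                   np.zeros((k, 0)), np.zeros((k, 0, 0, 0), np.float32),
                   np.full(k, -1, np.int64), np.zeros(k, np.int8))


def make_singles(batch, model: OpticalModel, geom: ScannerGeometry,
                 cfg: DAQConfig, noise: NoiseConfig, rng) -> SinglesBatch:
    """Run optics + trigger over an EventBatch and emit the singles stream."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    keys, maps = chain_expected_maps(batch, model, geom)
    gain = make_gain_map(geom, noise)
    signals = sample_signals(maps, rng, noise, gain)
    arrays, fsums = apply_thresholds(signals, cfg)
    fired = fsums.max(axis=1) > 0
    facet = np.argmax(fsums, axis=1)

    # chain time = first interaction time of the photon
    first = batch.rec_order == 0
    t_first = np.full((batch.n_events, 2), np.nan)
    t_first[batch.rec_event[first], batch.rec_photon[first]] = batch.rec_time[first]
    times = t_first[keys[:, 0], keys[:, 1]]

    nf = geom.n_facets
    sel = np.stack([(facet - 1) % nf, facet, (facet + 1) % nf], axis=1)
    idx = np.arange(keys.shape[0])
    maps3 = signals[idx[:, None], sel]

    sb = SinglesBatch(
        times=times[fired],
        facets=facet[fired],
        facet_sums=fsums[fired, facet[fired]],
        array_sums=arrays[fired, facet[fired]],
        maps3=maps3[fired].astype(np.float32),
        truth_event=keys[fired, 0].astype(np.int64),
        truth_photon=keys[fired, 1].astype(np.int8),
    )
    if cfg.intrinsic_singles_rate > 0 and sb.n > 1:
        sb = _add_intrinsic_singles(sb, geom, cfg, noise, rng)
    return sb.sort_by_time()


def _add_intrinsic_singles(sb: SinglesBatch, geom, cfg, noise, rng) -> SinglesBatch:
    """Flat Poisson background singles (intrinsic LYSO activity stand-in)."""
    t0, t1 = float(sb.times.min()), float(sb.times.max())
    span_s = (t1 - t0) / 1e9
    nf = geom.n_facets
    n_bg = rng.poisson(cfg.intrinsic_singles_rate * span_s * nf)
    if n_bg == 0:
        return sb
    times = rng.uniform(t0, t1, n_bg)
    facets = rng.integers(0, nf, n_bg)
    maps3 = rng.poisson(noise.dark_mean, (n_bg, 3, 4, 16)).astype(np.float32)
    # give the triggering array a just-above-threshold sum
    amp = cfg.array_threshold + rng.exponential(cfg.array_threshold, n_bg)
    maps3[:, 1, :, :4] += (amp[:, None, None] / 16.0).astype(np.float32)
    arrays = np.zeros((n_bg, 4))
    arrays[:, 0] = amp
    return SinglesBatch(
        times=np.concatenate([sb.times, times]),
        facets=np.concatenate([sb.facets, facets]),
        facet_sums=np.concatenate([sb.facet_sums, amp]),
        array_sums=np.concatenate([sb.array_sums, arrays]),
        maps3=np.concatenate([sb.maps3, maps3]),
        truth_event=np.concatenate([sb.truth_event, np.full(n_bg, -1, np.int64)]),
        truth_photon=np.concatenate([sb.truth_photon, np.zeros(n_bg, np.int8)]),
    )


@dataclass
class CoincidenceBatch:
    """Accepted prompt coincidences with their two 12 x 16 distributions."""

    times: np.ndarray         # (m,) ns
    primary: np.ndarray       # (m,) facet id
    secondary: np.ndarray     # (m,) facet id
    dists: np.ndarray         # (m, 2, 12, 16) float32 (primary, secondary)
    truth_event: np.ndarray   # (m, 2) int64
    truth_photon: np.ndarray  # (m, 2) int8
    # bookkeeping from the singles scan
    singles_counts: np.ndarray = field(default=None)  # (nf,)
    n_multiple_discarded: int = 0
    n_nonpartner: int = 0

    @property
    def n(self) -> int:
        return self.times.size


def assemble_distribution(maps3: np.ndarray) -> np.ndarray:
    """(…, 3, 4, 16) three-facet maps -> (…, 12, 16) distributions.

    Transaxial index 0-11 runs across (previous, primary, next) facets in
    increasing azimuth, axial index 0-15 in +z.
    """
    m = np.asarray(maps3)
    return m.reshape(*m.shape[:-3], 12, 16)


def find_coincidences(singles: SinglesBatch, cfg: DAQConfig,
                      geom: ScannerGeometry) -> CoincidenceBatch:
    """Scan the time-sorted singles stream for prompt coincidences.

    Two singles on partner facets with |dt| <= window/2 (full-width window)
    form a prompt; clusters of three or more in-window singles are
    discarded entirely.
    """
    t = singles.times
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("singles timeline must be time-sorted")
    w = cfg.coincidence_window_ns / 2.0
    n = singles.n
    pair_a, pair_b = [], []
    n_multi = 0
    n_nonpartner = 0
    i = 0
    while i < n - 1:
        j = np.searchsorted(t, t[i] + w, side="right")
        count = j - i
        if count == 1:
            i += 1
            continue
        if count == 2:
            a, b = i, i + 1
            if geom.are_partners(int(singles.facets[a]), int(singles.facets[b])):
                pair_a.append(a)
                pair_b.append(b)
            else:
                n_nonpartner += 1
            i += 2
        else:
            n_multi += 1
            i = j
    pa = np.asarray(pair_a, int)
    pb = np.asarray(pair_b, int)

    # primary = larger facet sum; order-invariant
    swap = singles.facet_sums[pb] > singles.facet_sums[pa]
    prim = np.where(swap, pb, pa)
    seco = np.where(swap, pa, pb)
    if singles.maps3.size:
        dists = np.stack([assemble_distribution(singles.maps3[prim]),
                          assemble_distribution(singles.maps3[seco])], axis=1)
    else:  # map-less timelines (rate studies)
        dists = np.zeros((prim.size, 2, 12, 16), np.float32)
    return CoincidenceBatch(
        times=singles.times[prim],
        primary=singles.facets[prim],
        secondary=singles.facets[seco],
        dists=dists,
        truth_event=np.stack([singles.truth_event[prim],
                              singles.truth_event[seco]], axis=1),
        truth_photon=np.stack([singles.truth_photon[prim],
                               singles.truth_photon[seco]], axis=1),
        singles_counts=singles.facet_counts(geom.n_facets),
        n_multiple_discarded=n_multi,
        n_nonpartner=n_nonpartner,
    )


def classify_prompts(coinc: CoincidenceBatch, batch) -> dict:
    """Split prompts into trues / scatters / randoms using truth links.

    A prompt is *true* when both singles stem from the two photons of the
    same annihilation with no Compton scatter in the object, *scattered*
    when same event but at least one photon object-scattered, and *random*
    otherwise.  The three counts sum exactly to the prompt count.
    """
    same = (coinc.truth_event[:, 0] == coinc.truth_event[:, 1]) \
        & (coinc.truth_event[:, 0] >= 0) \
        & (coinc.truth_photon[:, 0] != coinc.truth_photon[:, 1])
    ev = np.where(coinc.truth_event[:, 0] >= 0, coinc.truth_event[:, 0], 0)
    scattered = batch.object_scattered[ev].any(axis=1) & same
    trues = same & ~scattered
    randoms = ~same
    return {
        "prompts": int(coinc.n),
        "trues": int(trues.sum()),
        "scatters": int(scattered.sum()),
        "randoms": int(randoms.sum()),
        "true_mask": trues,
        "scatter_mask": scattered,
        "random_mask": randoms,
    }
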