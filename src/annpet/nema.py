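"""NEMA NU4-2008 performance analyses.

Implements the four report sections used for small-animal PET scanners:

* spatial resolution: FWHM / FWTM of point-source images along the radial,
  tangential and axial axes, from 1-D response functions summed over a
  window of +/- 2 x FWHM in the orthogonal directions (two passes), with a
  parabolic peak fit through the three highest samples and linear
  interpolation at the half / tenth crossings;
* detection sensitivity: background-subtracted rates per axial position
  divided by source activity, converted to absolute sensitivity with the
  positron branching ratio (0.9060 for Na-22);
* count rates: trues / scatter / randoms decomposition of summed sinogram
  profiles with the 14 mm central strip rule, NECR = T^2 / (T + S + R),
  peak NECR by parabolic interpolation over the activity sweep, and scatter
  fraction from low-rate acquisitions;
* image quality: uniformity VOI statistics, hot-rod recovery coefficients
  with the combined percent-standard-deviation rule, and spillover ratios
  in the cold chambers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantoms import NUCLIDES, IQPhantomSpec
from .recon import ImageVolume

__all__ = [
    "resolution_metrics",
    "sensitivity_metrics",
    "countrate_metrics",
    "iq_metrics",
    "profile_widths",
]


# ---------------------------------------------------------------------------
# spatial resolution


def _width_at(profile: np.ndarray, coords: np.ndarray, level: float,
              peak_idx: int) -> float:
    """Width of ``profile`` at ``level`` by linear interpolation."""
    above = profile >= level
    if not above[peak_idx]:
        raise ValueError("peak below requested level")
    i = peak_idx
    while i > 0 and above[i - 1]:
        i -= 1
    if i == 0 and above[0]:
        left = coords[0]
    else:
        f = (level - profile[i - 1]) / (profile[i] - profile[i - 1])
        left = coords[i - 1] + f * (coords[i] - coords[i - 1])
    j = peak_idx
    while j < profile.size - 1 and above[j + 1]:
        j += 1
    if j == profile.size - 1 and above[-1]:
        right = coords[-1]
    else:
        f = (level - profile[j + 1]) / (profile[j] - profile[j + 1])
        right = coords[j + 1] - f * (coords[j + 1] - coords[j])
    return float(right - left)


def profile_widths(profile: np.ndarray, coords: np.ndarray) -> dict:
    """FWHM and FWTM of a 1-D response function.

    Peak amplitude from a parabola through the maximum sample and its two
    neighbours; widths from linear interpolation between the bracketing
    samples (no function fitting).
    """
    profile = np.asarray(profile, float)
    k = int(np.argmax(profile))
    if profile[k] <= 0:
        raise ValueError("no peak found in profile")
    if 0 < k < profile.size - 1:
        y0, y1, y2 = profile[k - 1], profile[k], profile[k + 1]
        denom = y0 - 2 * y1 + y2
        peak = y1 - 0.125 * (y0 - y2) ** 2 / denom if denom < 0 else y1
    else:
        peak = profile[k]
    return {
        "peak": float(peak),
        "fwhm": _width_at(profile, coords, peak / 2.0, k),
        "fwtm": _width_at(profile, coords, peak / 10.0, k),
    }


def resolution_metrics(volume: ImageVolume, source_position,
                       axis_names: tuple[str, str, str] = ("radial", "tangential", "axial"),
                       initial_window_mm: float = 4.0) -> dict:
    """NU4 spatial resolution of a point-source image.

    The volume axes are taken as (radial, tangential, axial) — place the
    source on the +x axis so the image x direction is radial.  For each axis
    the response function sums the orthogonal directions over +/- 2 x FWHM
    around the peak, iterated from an initial window.
    """
    vals = np.asarray(volume.values, float)
    if vals.max() <= 0:
        raise ValueError("no peak found in volume")
    axes_coords = volume.voxel_centers()
    peak = np.unravel_index(np.argmax(vals), vals.shape)

    results = {}
    for ax in range(3):
        others = [a for a in range(3) if a != ax]
        widths = {o: initial_window_mm for o in others}
        out = None
        for _pass in range(2):
            mask = np.ones(vals.shape, bool)
            for o in others:
                c = axes_coords[o]
                center = c[peak[o]]
                half = 2.0 * widths[o] if _pass else widths[o]
                sel = np.abs(c - center) <= half
                mask &= np.moveaxis(
                    np.broadcast_to(sel, [vals.shape[a] for a in (0, 1, 2) if a != o] + [vals.shape[o]]),
                    -1, o)
            prof = np.where(mask, vals, 0.0).sum(axis=tuple(others))
            out = profile_widths(prof, axes_coords[ax])
            for o in others:
                widths[o] = out["fwhm"] / 2.0 + volume.voxel_size[o]
        results[axis_names[ax]] = {k: out[k] for k in ("fwhm", "fwtm")}
    results["source_position"] = list(np.asarray(source_position, float))
    return results


# ---------------------------------------------------------------------------
# sensitivity


def sensitivity_metrics(rates, background_rate: float, activity_bq: float,
                        nuclide: str = "Na22") -> dict:
    """NU4 detection sensitivity from background-subtracted count rates.

    ``rates``: prompt rates (cps) per axial source position; S_i =
    (R_i - R_B) / A; absolute sensitivity divides by the positron branching
    fraction.  ``integrated`` sums S_i over the measured positions.
    """
    if activity_bq <= 0:
        raise ValueError("calibrated activity must be > 0")
    branching = NUCLIDES[nuclide].positron_branching
    rates = np.atleast_1d(np.asarray(rates, float))
    S = np.maximum(rates - background_rate, 0.0) / activity_bq
    SA = S / branching * 100.0
    return {
        "per_position_cps_per_bq": S.tolist(),
        "per_position_absolute_pct": SA.tolist(),
        "peak_cps_per_bq": float(S.max()),
        "peak_absolute_pct": float(SA.max()),
        "integrated_cps_per_bq": float(S.sum()),
        "integrated_absolute_pct": float(S.sum() / branching * 100.0),
        "branching": branching,
    }


# ---------------------------------------------------------------------------
# count rates


def _strip_decomposition(sino2d: np.ndarray, r_bin: float, r_max: float,
                         phantom_radius: float, edge_margin: float = 8.0,
                         strip_half_mm: float = 7.0):
    """NU4 profile analysis of one summed (radial x angle) sinogram.

    Returns (total counts inside the phantom band, background counts =
    scatter + randoms) using the centred 14 mm strip and linear background
    interpolation beneath it.
    """
    n_r, n_a = sino2d.shape
    centers = (np.arange(n_r) + 0.5) * r_bin - r_max
    sino = sino2d.copy()
    sino[np.abs(centers) > phantom_radius + edge_margin, :] = 0.0

    # align the maximum of every angular profile to the centre bin
    mid = n_r // 2
    aligned = np.empty_like(sino)
    for a in range(n_a):
        shift = mid - int(np.argmax(sino[:, a]))
        aligned[:, a] = np.roll(sino[:, a], shift)
    prof = aligned.sum(axis=1)

    total = float(prof.sum())
    # counts at +/- strip_half by linear interpolation
    cl = float(np.interp(-strip_half_mm, centers, prof))
    cr = float(np.interp(strip_half_mm, centers, prof))
    inside = np.abs(centers) < strip_half_mm
    n_inside = 2.0 * strip_half_mm / r_bin
    bg_under = 0.5 * (cl + cr) * n_inside
    outside = float(prof[~inside].sum())
    background = outside + bg_under
    return total, min(background, total)


def countrate_metrics(sinograms, activities_bq, acq_times_s,
                      randoms_rates=None, phantom_radius: float = 12.5,
                      r_bin: float | None = None, r_max: float | None = None) -> dict:
    """NU4 count-rate performance over an activity sweep.

    ``sinograms``: per-acquisition summed 2-D (radial x angle) arrays or
    :class:`SSRBSinogram` objects.  ``randoms_rates``: expected randoms (cps)
    per acquisition (singles-based estimate or truth), default zero.
    NECR = T^2 / (T + S + R); peak NECR by parabolic interpolation over
    activity; scatter fraction from acquisitions with R < 1 % of T.
    """
    n = len(sinograms)
    if n < 2:
        raise ValueError("need at least two acquisitions at distinct activities")
    activities = np.asarray(activities_bq, float)
    acq_times = np.broadcast_to(np.asarray(acq_times_s, float), (n,))
    randoms = np.zeros(n) if randoms_rates is None else np.asarray(randoms_rates, float)

    rows = []
    for k in range(n):
        s = sinograms[k]
        if hasattr(s, "counts"):
            arr = s.counts.sum(axis=0)
            rb, rm = s.spec.r_bin, s.spec.r_max
        else:
            arr = np.asarray(s, float)
            rb, rm = r_bin, r_max
            if rb is None or rm is None:
                raise ValueError("r_bin/r_max required for raw sinogram arrays")
        if rm < phantom_radius + 8.0:
            raise ValueError("phantom edge outside sinogram support")
        total_c, bg_c = _strip_decomposition(arr, rb, rm, phantom_radius)
        T = (total_c - bg_c) / acq_times[k]
        R = min(randoms[k], bg_c / acq_times[k])
        S = bg_c / acq_times[k] - R
        total_rate = total_c / acq_times[k]
        necr = T**2 / total_rate if total_rate > 0 else 0.0
        rows.append({"activity_bq": float(activities[k]), "trues_cps": T,
                     "scatter_cps": S, "randoms_cps": R,
                     "total_cps": total_rate, "necr_cps": necr})

    necr = np.array([r["necr_cps"] for r in rows])
    act = activities
    k = int(np.argmax(necr))
    if 0 < k < n - 1:  # parabolic peak interpolation over the sweep
        y0, y1, y2 = necr[k - 1], necr[k], necr[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            dx = 0.5 * (y0 - y2) / denom
            peak_necr = y1 - 0.25 * (y0 - y2) * dx
            peak_act = float(np.interp(k + dx, np.arange(n), act))
        else:
            peak_necr, peak_act = y1, act[k]
    else:
        peak_necr, peak_act = necr[k], act[k]

    lowrate = [r for r in rows
               if r["randoms_cps"] < 0.01 * max(r["trues_cps"], 1e-12)]
    if lowrate:
        sT = sum(r["trues_cps"] for r in lowrate)
        sS = sum(r["scatter_cps"] for r in lowrate)
        sf = sS / (sT + sS) if sT + sS > 0 else float("nan")
    else:
        sf = float("nan")
    return {"acquisitions": rows, "peak_necr_cps": float(peak_necr),
            "peak_necr_activity_bq": float(peak_act),
            "scatter_fraction": float(sf)}


# ---------------------------------------------------------------------------
# image quality


def _cyl_mask(volume: ImageVolume, center_xy, diameter, z_range):
    xs, ys, zs = volume.voxel_centers()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    trans = ((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2
             <= (diameter / 2.0) ** 2)
    axial = (zs >= z_range[0]) & (zs <= z_range[1])
    return trans[:, :, None] & axial[None, None, :]


def iq_metrics(volume: ImageVolume, phantom: IQPhantomSpec,
               uniformity_diameter: float = 22.5,
               uniformity_length: float = 10.0,
               sor_diameter: float = 4.0, sor_length: float = 7.5,
               rc_slab_mm: float = 10.0) -> dict:
    """NU4 image-quality report: uniformity, recovery coefficients, SOR."""
    if phantom is None:
        raise ValueError("phantom registration required")
    vals = np.asarray(volume.values, float)
    xs, ys, zs = volume.voxel_centers()

    zu0, zu1 = phantom.uniform_zrange
    zmid = 0.5 * (zu0 + zu1)
    uni_mask = _cyl_mask(volume, (0.0, 0.0), uniformity_diameter,
                         (zmid - uniformity_length / 2, zmid + uniformity_length / 2))
    uni = vals[uni_mask]
    if uni.size == 0:
        raise ValueError("uniformity VOI is empty on this grid")
    uni_mean = float(uni.mean())
    uniformity = {"mean": uni_mean, "max": float(uni.max()),
                  "min": float(uni.min()),
                  "pct_std": float(100.0 * uni.std(ddof=0) / uni_mean)}
    uni_rel_std = uni.std(ddof=0) / uni_mean

    # recovery coefficients
    zr0, zr1 = phantom.rod_zrange
    zc = 0.5 * (zr0 + zr1)
    slab_sel = (zs >= zc - rc_slab_mm / 2) & (zs <= zc + rc_slab_mm / 2)
    slab = vals[:, :, slab_sel].mean(axis=2)
    rc = {}
    for dia, (cx, cy) in zip(phantom.rod_diameters, phantom.rod_centers()):
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        roi = (X - cx) ** 2 + (Y - cy) ** 2 <= dia**2  # 2x diameter circle
        if not roi.any():
            rc[f"{dia:.0f}mm"] = None
            continue
        flat = np.where(roi, slab, -np.inf)
        ix, iy = np.unravel_index(np.argmax(flat), flat.shape)
        prof = vals[ix, iy, slab_sel]
        mean_p = float(prof.mean())
        rc_val = mean_p / uni_mean
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = prof.std(ddof=0) / mean_p if mean_p > 0 else np.nan
        pct = 100.0 * math.sqrt(rel**2 + uni_rel_std**2) if np.isfinite(rel) else float("nan")
        rc[f"{dia:.0f}mm"] = {"rc": float(rc_val), "pct_std": float(pct)}

    # spillover ratios
    zc0, zc1 = phantom.cold_zrange
    zm = 0.5 * (zc0 + zc1)
    sor = {}
    for (cx, cy), name in zip(phantom.cold_centers(), ("water", "air")):
        mask = _cyl_mask(volume, (cx, cy), sor_diameter,
                         (zm - sor_length / 2, zm + sor_length / 2))
        voi = vals[mask]
        if voi.size == 0:
            sor[name] = None
            continue
        m = float(voi.mean())
        rel = voi.std(ddof=0) / m if m > 0 else 0.0
        sor[name] = {"sor": m / uni_mean,
                     "pct_std": float(100.0 * math.sqrt(rel**2 + uni_rel_std**2))}

    return {"uniformity": uniformity, "recovery_coefficients": rc,
            "spillover_ratios": sor}
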