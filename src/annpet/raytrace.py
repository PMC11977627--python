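"""Numba kernels: voxel-grid line integrals and list-mode MLEM sweeps.

All kernels use an Amanatides-Woo style exact voxel traversal on a
world-aligned grid with isotropic voxels.  They are shared by the photon
transport (attenuation path integrals), the recon module (attenuation
weights, MLEM forward/back projection, sensitivity image) and tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grid_line_integral", "grid_line_integrals", "mlem_iterate", "accumulate_sensitivity"]


@njit(cache=True)
def _traverse_accum(p0, p1, origin, voxel, shape, values):
    """Line integral of ``values`` along segment p0->p1 (exact traversal)."""
    d = np.empty(3)
    for i in range(3):
        d[i] = p1[i] - p0[i]
    seg_len = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    if seg_len <= 0.0:
        return 0.0
    # clip [t0, t1] to the grid box
    t0, t1 = 0.0, 1.0
    for i in range(3):
        lo = origin[i]
        hi = origin[i] + shape[i] * voxel
        if d[i] != 0.0:
            ta = (lo - p0[i]) / d[i]
            tb = (hi - p0[i]) / d[i]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
        else:
            if p0[i] < lo or p0[i] > hi:
                return 0.0
    if t1 <= t0:
        return 0.0
    total = 0.0
    # entry voxel
    ix = np.empty(3, np.int64)
    t = t0 + 1e-12
    for i in range(3):
        ix[i] = int((p0[i] + t * d[i] - origin[i]) / voxel)
        if ix[i] < 0:
            ix[i] = 0
        if ix[i] >= shape[i]:
            ix[i] = shape[i] - 1
    t_next = np.empty(3)
    step = np.empty(3, np.int64)
    dt = np.empty(3)
    for i in range(3):
        if d[i] > 0:
            step[i] = 1
            t_next[i] = ((ix[i] + 1) * voxel + origin[i] - p0[i]) / d[i]
            dt[i] = voxel / d[i]
        elif d[i] < 0:
            step[i] = -1
            t_next[i] = (ix[i] * voxel + origin[i] - p0[i]) / d[i]
            dt[i] = -voxel / d[i]
        else:
            step[i] = 0
            t_next[i] = 1e30
            dt[i] = 1e30
    t = t0
    while t < t1:
        # next boundary
        k = 0
        tn = t_next[0]
        if t_next[1] < tn:
            k = 1
            tn = t_next[1]
        if t_next[2] < tn:
            k = 2
            tn = t_next[2]
        t_end = tn if tn < t1 else t1
        total += values[ix[0], ix[1], ix[2]] * (t_end - t) * seg_len
        t = t_end
        if tn >= t1:
            break
        ix[k] += step[k]
        if ix[k] < 0 or ix[k] >= shape[k]:
            break
        t_next[k] += dt[k]
    return total


@njit(cache=True)
def grid_line_integral(p0, p1, origin, voxel, values):
    shape = np.array(values.shape, np.int64)
    return _traverse_accum(p0, p1, origin, voxel, shape, values)


@njit(cache=True)
def grid_line_integrals(P0, P1, origin, voxel, values):
    n = P0.shape[0]
    out = np.empty(n)
    shape = np.array(values.shape, np.int64)
    for i in range(n):
        out[i] = _traverse_accum(P0[i], P1[i], origin, voxel, shape, values)
    return out


@njit(cache=True)
def _ray_voxels(p0, p1, origin, voxel, shape, idx_buf, len_buf):
    """Collect (flat voxel index, intersection length) pairs along a segment.

    Returns the number of voxels written into the buffers.
    """
    d = np.empty(3)
    for i in range(3):
        d[i] = p1[i] - p0[i]
    seg_len = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    if seg_len <= 0.0:
        return 0
    t0, t1 = 0.0, 1.0
    for i in range(3):
        lo = origin[i]
        hi = origin[i] + shape[i] * voxel
        if d[i] != 0.0:
            ta = (lo - p0[i]) / d[i]
            tb = (hi - p0[i]) / d[i]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
        else:
            if p0[i] < lo or p0[i] > hi:
                return 0
    if t1 <= t0:
        return 0
    ix = np.empty(3, np.int64)
    t = t0 + 1e-12
    for i in range(3):
        ix[i] = int((p0[i] + t * d[i] - origin[i]) / voxel)
        if ix[i] < 0:
            ix[i] = 0
        if ix[i] >= shape[i]:
            ix[i] = shape[i] - 1
    t_next = np.empty(3)
    step = np.empty(3, np.int64)
    dt = np.empty(3)
    for i in range(3):
        if d[i] > 0:
            step[i] = 1
            t_next[i] = ((ix[i] + 1) * voxel + origin[i] - p0[i]) / d[i]
            dt[i] = voxel / d[i]
        elif d[i] < 0:
            step[i] = -1
            t_next[i] = (ix[i] * voxel + origin[i] - p0[i]) / d[i]
            dt[i] = -voxel / d[i]
        else:
            step[i] = 0
            t_next[i] = 1e30
            dt[i] = 1e30
    t = t0
    count = 0
    nmax = idx_buf.shape[0]
    while t < t1 and count < nmax:
        k = 0
        tn = t_next[0]
        if t_next[1] < tn:
            k = 1
            tn = t_next[1]
        if t_next[2] < tn:
            k = 2
            tn = t_next[2]
        t_end = tn if tn < t1 else t1
        flat = (ix[0] * shape[1] + ix[1]) * shape[2] + ix[2]
        idx_buf[count] = flat
        len_buf[count] = (t_end - t) * seg_len
        count += 1
        t = t_end
        if tn >= t1:
            break
        ix[k] += step[k]
        if ix[k] < 0 or ix[k] >= shape[k]:
            break
        t_next[k] += dt[k]
    return count


@njit(cache=True)
def mlem_iterate(P0, P1, surv, bg, lam_flat, sens_flat, origin, voxel, shape):
    """One list-mode MLEM multiplicative update.

    Model for event i (one count each): ybar_i = surv_i * <a_i, lam> + bg_i,
    with a_i the voxel intersection lengths of the LOR chord.  Returns the
    updated image (flat) and the Poisson log-likelihood contribution
    sum_i log(ybar_i) evaluated at the *input* image.
    """
    n = P0.shape[0]
    nvox = lam_flat.shape[0]
    acc = np.zeros(nvox)
    loglik = 0.0
    maxbuf = shape[0] + shape[1] + shape[2] + 3
    idx_buf = np.empty(maxbuf, np.int64)
    len_buf = np.empty(maxbuf)
    for i in range(n):
        m = _ray_voxels(P0[i], P1[i], origin, voxel, shape, idx_buf, len_buf)
        if m == 0:
            continue
        fwd = 0.0
        for j in range(m):
            fwd += len_buf[j] * lam_flat[idx_buf[j]]
        ybar = surv[i] * fwd + bg[i]
        if ybar <= 1e-300:
            continue
        loglik += np.log(ybar)
        w = surv[i] / ybar
        for j in range(m):
            acc[idx_buf[j]] += len_buf[j] * w
    new = np.empty(nvox)
    for v in range(nvox):
        if sens_flat[v] > 0.0:
            new[v] = lam_flat[v] * acc[v] / sens_flat[v]
        else:
            new[v] = 0.0
    return new, loglik


@njit(cache=True)
def accumulate_sensitivity(P0, P1, surv, sens_flat, origin, voxel, shape):
    """Add surv-weighted intersection lengths of each ray into ``sens_flat``."""
    n = P0.shape[0]
    maxbuf = shape[0] + shape[1] + shape[2] + 3
    idx_buf = np.empty(maxbuf, np.int64)
    len_buf = np.empty(maxbuf)
    for i in range(n):
        m = _ray_voxels(P0[i], P1[i], origin, voxel, shape, idx_buf, len_buf)
        for j in range(m):
            sens_flat[idx_buf[j]] += surv[i] * len_buf[j]
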