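"""Numba inner loops for the reconstruction hot paths.

All kernels accumulate in float64 regardless of the stored matrix dtype,
so EM updates are the exact multiplicative updates for the (float32)
system matrix actually used and the Poisson log-likelihood bookkeeping
is reliable at 1e-12 relative.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "gaussian_row",
    "csr_subset_update",
    "csr_matvec",
    "csr_colsum",
]


@njit(cache=True)
def gaussian_row(centers, apex, axis, half_angle_deg, sigma_deg, cutoff_deg, band_deg,
                 out_idx, out_val, out_cand):
    """Transition row (and SOE candidate set) of one cone over all pixels.

    Gaussian-ARM fast path: weight = N(resid; sigma)/r^2 for residuals
    within cutoff_deg, zero outside. Pixels with residual <= band_deg are
    additionally collected as SOE candidates. Returns (n_row, n_cand).
    """
    n = centers.shape[0]
    ax, ay, az = apex[0], apex[1], apex[2]
    ux, uy, uz = axis[0], axis[1], axis[2]
    norm = 1.0 / (sigma_deg * math.sqrt(2.0 * math.pi))
    inv2s2 = 0.5 / (sigma_deg * sigma_deg)
    n_row = 0
    n_cand = 0
    for j in range(n):
        dx = centers[j, 0] - ax
        dy = centers[j, 1] - ay
        dz = centers[j, 2] - az
        r2 = dx * dx + dy * dy + dz * dz
        c = (dx * ux + dy * uy + dz * uz) / math.sqrt(r2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        resid = abs(math.degrees(math.acos(c)) - half_angle_deg)
        if resid <= cutoff_deg:
            out_idx[n_row] = j
            out_val[n_row] = norm * math.exp(-resid * resid * inv2s2) / r2
            n_row += 1
        if resid <= band_deg:
            out_cand[n_cand] = j
            n_cand += 1
    return n_row, n_cand


@njit(cache=True)
def csr_subset_update(indptr, indices, data, rows, lam, acc):
    """One ordered-subset EM accumulation pass.

    For each event row i in `rows`: forward-project f = t_i . lam and add
    t_i / f into acc. Rows with f <= 0 are skipped; returns their count.
    acc must come in zeroed.
    """
    skipped = 0
    for ri in range(rows.size):
        i = rows[ri]
        lo = indptr[i]
        hi = indptr[i + 1]
        f = 0.0
        for k in range(lo, hi):
            f += data[k] * lam[indices[k]]
        if f <= 0.0:
            skipped += 1
            continue
        inv = 1.0 / f
        for k in range(lo, hi):
            acc[indices[k]] += data[k] * inv
    return skipped


@njit(cache=True)
def csr_matvec(indptr, indices, data, x, out):
    for i in range(indptr.size - 1):
        s = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            s += data[k] * x[indices[k]]
        out[i] = s


@njit(cache=True)
def csr_colsum(indptr, indices, data, out):
    for k in range(indices.size):
        out[indices[k]] += data[k]
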