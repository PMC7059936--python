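"""Event-to-cone conversion, transition rows, backprojection, and the
analytic sensitivity map.

Each valid event defines a Compton cone: apex at the scatter position,
axis along the reversed scattered-photon direction (absorber hit ->
scatter hit), half-angle from the Compton relation. The transition
weight of event i at pixel j is

    t_ij = |D|^-2 * V(theta_ij; sigma, gamma)

where D is the vector from the cone apex to the pixel centre (the
inverse-square factor corrects the near-field distance effect), V is the
ARM Voigt kernel, and theta_ij is the angular distance of the pixel
direction from the cone surface. Simple backprojection is the sum of
transition rows over events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .events import DetectorSpec, EventList
from .grid import Image, ImageGrid, normalize
from .physics import ArmModel, klein_nishina_weight, scatter_angle_from_energies

__all__ = [
    "ConeRecord",
    "ConeSet",
    "event_to_cone",
    "cones_from_events",
    "angular_residual",
    "signed_angular_residual",
    "transition_row",
    "backproject",
    "sensitivity_map",
    "si_solid_angle",
    "ConeSystem",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_FWHM = 5.0  # transition weights truncated beyond this many ARM FWHM


@dataclass(frozen=True)
class ConeRecord:
    """Apex/axis/half-angle representation of one event's Compton cone.

    half_angle is NaN for kinematically forbidden events (the event is
    flagged rather than raising, so acquisition chains can drop it).
    """

    apex: np.ndarray  # (3,), mm
    axis: np.ndarray  # (3,), unit
    half_angle: float  # degrees

    @property
    def valid(self) -> bool:
        return np.isfinite(self.half_angle) and 0.0 < self.half_angle < 180.0


class ConeSet:
    """Vectorized cones for an event list, with a validity mask."""

    def __init__(self, apex: np.ndarray, axis: np.ndarray, half_angle: np.ndarray) -> None:
        self.apex = apex
        self.axis = axis
        self.half_angle = half_angle

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.half_angle) & (self.half_angle > 0) & (self.half_angle < 180)

    def __len__(self) -> int:
        return len(self.half_angle)

    def __getitem__(self, i: int) -> ConeRecord:
        return ConeRecord(self.apex[i], self.axis[i], float(self.half_angle[i]))


def cones_from_events(events: EventList) -> ConeSet:
    axis = events.scatter - events.absorber
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("coincident scatter/absorber positions")
    return ConeSet(
        events.scatter.copy(), axis / norm, scatter_angle_from_energies(events.e1, events.e2)
    )


def event_to_cone(event) -> ConeRecord:
    """Cone of a single event; invalid kinematics give half_angle = NaN."""
    apex = np.asarray(event.scatter_pos, dtype=float)
    absorb = np.asarray(event.absorber_pos, dtype=float)
    axis = apex - absorb
    axis = axis / np.linalg.norm(axis)
    return ConeRecord(apex, axis, scatter_angle_from_energies(event.e1, event.e2))


def _cos_alpha(cone_apex: np.ndarray, cone_axis: np.ndarray, points: np.ndarray) -> np.ndarray:
    d = np.atleast_2d(points) - cone_apex
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise ValueError("point coincides with the cone apex")
    return np.clip(d @ cone_axis / r, -1.0, 1.0)


def signed_angular_residual(cone: ConeRecord, points: np.ndarray) -> np.ndarray | float:
    """alpha - half_angle (degrees), where alpha is the angle between the
    cone axis and the apex->point direction. Used for ARM histograms."""
    alpha = np.degrees(np.arccos(_cos_alpha(cone.apex, cone.axis, points)))
    out = alpha - cone.half_angle
    return float(out[0]) if np.asarray(points).ndim == 1 else out


def angular_residual(cone: ConeRecord, points: np.ndarray) -> np.ndarray | float:
    """Minimum angular distance (degrees) from the apex->point direction
    to the cone surface: |alpha - half_angle|."""
    return np.abs(signed_angular_residual(cone, points))


def transition_row(
    cone: ConeRecord,
    grid: ImageGrid,
    arm: ArmModel,
    cutoff_fwhm: float = DEFAULT_CUTOFF_FWHM,
) -> np.ndarray:
    """Transition weights t_ij of one cone over all pixels (flat, row-major).

    Weights beyond cutoff_fwhm ARM FWHM of angular residual are set to
    zero to keep rows sparse (at the default 5 FWHM the discarded Voigt
    mass is negligible for Gaussian-dominated ARMs).
    """
    if not cone.valid:
        raise ValueError("kinematically invalid cone")
    centers = grid.pixel_centers()
    d = centers - cone.apex
    r2 = np.einsum("ij,ij->i", d, d)
    cos_a = np.clip(d @ cone.axis / np.sqrt(r2), -1.0, 1.0)
    resid = np.abs(np.degrees(np.arccos(cos_a)) - cone.half_angle)
    out = np.zeros(grid.n_pixels)
    inside = resid <= cutoff_fwhm * arm.fwhm
    out[inside] = arm.density(resid[inside]) / r2[inside]
    return out


class ConeSystem:
    """Cached sparse transition rows for an event list on a grid.

    Rows of invalid (kinematically forbidden) or empty events are kept in
    the matrix as all-zero so row index == event index; reconstruction
    code skips them via zero forward projections. `valid` records which
    events contributed weight.

    When candidate_band (degrees) is given, the pixels within that
    angular residual of each cone are collected as SOE candidate sets in
    the same pass (cand_idx/cand_ptr, CSR layout over all events).
    """

    def __init__(
        self,
        events: EventList,
        grid: ImageGrid,
        arm: ArmModel,
        cutoff_fwhm: float = DEFAULT_CUTOFF_FWHM,
        dtype=np.float32,
        candidate_band: float | None = None,
    ) -> None:
        from ._kernels import gaussian_row

        self.events = events
        self.grid = grid
        self.arm = arm
        self.cutoff_fwhm = cutoff_fwhm
        cones = cones_from_events(events)
        self.cones = cones
        n = len(events)
        npix = grid.n_pixels
        band = -1.0 if candidate_band is None else float(candidate_band)

        centers = grid.pixel_centers()
        cutoff = cutoff_fwhm * arm.fwhm
        indptr = np.zeros(n + 1, dtype=np.int64)
        cand_parts: list[np.ndarray] = []
        cand_ptr = np.zeros(n + 1, dtype=np.int64)
        valid = cones.valid
        use_fast = arm.gamma == 0.0
        buf_idx = np.empty(npix, dtype=np.int32)
        buf_val = np.empty(npix, dtype=np.float64)
        buf_cand = np.empty(npix, dtype=np.int32)

        def _row(i: int) -> tuple[int, int]:
            """Fill the shared buffers with row i; returns (n_row, n_cand)."""
            if use_fast:
                return gaussian_row(
                    centers, cones.apex[i], cones.axis[i], cones.half_angle[i],
                    arm.sigma, cutoff, band, buf_idx, buf_val, buf_cand,
                )
            d = centers - cones.apex[i]
            r2 = np.einsum("ij,ij->i", d, d)
            cos_a = np.clip(d @ cones.axis[i] / np.sqrt(r2), -1.0, 1.0)
            resid = np.abs(np.degrees(np.arccos(cos_a)) - cones.half_angle[i])
            inside = np.flatnonzero(resid <= cutoff)
            buf_idx[: inside.size] = inside
            buf_val[: inside.size] = arm.density(resid[inside]) / r2[inside]
            n_cand = 0
            if band >= 0:
                cand = np.flatnonzero(resid <= band)
                n_cand = cand.size
                buf_cand[:n_cand] = cand
            return inside.size, n_cand

        # estimate capacity from a subsample, then fill preallocated arrays
        # (growing once by 25% if the estimate falls short) so the peak
        # memory is ~1x the final matrix, not 2x
        valid_idx = np.flatnonzero(valid)
        sample = valid_idx[:: max(1, len(valid_idx) // 128)][:128]
        est = int(np.mean([_row(i)[0] for i in sample])) if sample.size else 0
        capacity = int(est * max(1, valid_idx.size) * 1.15) + npix
        indices = np.empty(capacity, dtype=np.int32)
        values = np.empty(capacity, dtype=dtype)
        pos = 0
        for i in range(n):
            if not valid[i]:
                indptr[i + 1] = pos
                cand_ptr[i + 1] = cand_ptr[i]
                continue
            n_row, n_cand = _row(i)
            if pos + n_row > capacity:
                capacity = int(capacity * 1.25) + n_row
                indices = np.concatenate([indices[:pos], np.empty(capacity - pos, np.int32)])
                values = np.concatenate([values[:pos], np.empty(capacity - pos, dtype)])
            indices[pos : pos + n_row] = buf_idx[:n_row]
            values[pos : pos + n_row] = buf_val[:n_row]
            pos += n_row
            indptr[i + 1] = pos
            if band >= 0:
                cand_parts.append(buf_cand[:n_cand].copy())
                cand_ptr[i + 1] = cand_ptr[i] + n_cand
        indices.resize(pos, refcheck=False)  # in-place shrink, no copy
        values.resize(pos, refcheck=False)
        if pos < np.iinfo(np.int32).max:
            indptr = indptr.astype(np.int32)  # match index dtype, avoids upcast copy
        self.matrix = sp.csr_matrix((values, indices, indptr), shape=(n, npix))
        self.cand_idx = (
            np.concatenate(cand_parts).astype(np.int64)
            if band >= 0 and cand_parts
            else None
        )
        self.cand_ptr = cand_ptr if band >= 0 else None
        self.candidate_band = candidate_band
        self.valid = valid & (np.diff(indptr) > 0)
        n_dropped = int(n - self.valid.sum())
        if n_dropped:
            log.info("ConeSystem: %d of %d events carry no weight (invalid or off-FOV)",
                     n_dropped, n)

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    def forward(self, lam: np.ndarray) -> np.ndarray:
        """Forward projection t @ lam with float64 accumulation."""
        from ._kernels import csr_matvec

        out = np.empty(self.n_events)
        csr_matvec(
            self.matrix.indptr, self.matrix.indices, self.matrix.data,
            np.ascontiguousarray(lam, dtype=float), out,
        )
        return out

    def backprojection(self) -> np.ndarray:
        """Unnormalized BP raster (flat): column sums of the row cache,
        accumulated in float64."""
        from ._kernels import csr_colsum

        out = np.zeros(self.grid.n_pixels)
        csr_colsum(self.matrix.indptr, self.matrix.indices, self.matrix.data, out)
        return out


def backproject(
    events: EventList,
    grid: ImageGrid,
    arm: ArmModel,
    cutoff_fwhm: float = DEFAULT_CUTOFF_FWHM,
    system: ConeSystem | None = None,
) -> Image:
    """Simple backprojection: normalized sum of transition rows."""
    if system is None:
        system = ConeSystem(events, grid, arm, cutoff_fwhm)
    if not system.valid.any():
        raise ValueError("no valid events to backproject")
    flat = system.backprojection()
    return normalize(Image(grid, flat.reshape(grid.shape)))


# ---------------------------------------------------------------------------
# analytic sensitivity map


def si_solid_angle(points: np.ndarray, det: DetectorSpec, m_sub: int = 16) -> np.ndarray:
    """Solid angle (sr) of the Si active face seen from each point,
    by midpoint quadrature over an m_sub x m_sub subdivision."""
    points = np.atleast_2d(points)
    h = det.half_extent
    step = det.active_extent / m_sub
    c = -h + (np.arange(m_sub) + 0.5) * step
    sx, sy = np.meshgrid(c, c, indexing="ij")
    sub = np.column_stack([sx.ravel(), sy.ravel(), np.zeros(m_sub * m_sub)])
    d = points[:, None, :] - sub[None, :, :]  # (npts, m^2, 3)
    r = np.linalg.norm(d, axis=2)
    cos_t = np.abs(points[:, 2])[:, None] / r
    return (step * step * cos_t / r**2).sum(axis=1)


def _absorber_acceptance(
    points: np.ndarray,
    det: DetectorSpec,
    e_total: float,
    n_cos: int = 64,
    n_phi: int = 32,
) -> np.ndarray:
    """Klein–Nishina-weighted probability that the scattered ray from the
    scatterer centre hits any absorber layer, per source point."""
    points = np.atleast_2d(points)
    npts = len(points)
    # incident directions: source point -> scatterer centre (origin)
    d_inc_all = -points / np.linalg.norm(points, axis=1, keepdims=True)

    # Gauss-Legendre in cos(omega) over the full range, uniform azimuth
    nodes, weights = np.polynomial.legendre.leggauss(n_cos)
    kn = klein_nishina_weight(nodes, e_total) * weights
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    sin_w = np.sqrt(1.0 - nodes**2)
    h = det.half_extent
    layer_z = det.absorber_layer_z()

    out = np.empty(npts)
    chunk = max(1, 2**22 // (n_cos * n_phi))
    for lo in range(0, npts, chunk):
        d_inc = d_inc_all[lo : lo + chunk]
        # orthonormal basis perpendicular to each incident direction
        helper = np.zeros_like(d_inc)
        small = np.abs(d_inc[:, 0]) < 0.9
        helper[small, 0] = 1.0
        helper[~small, 1] = 1.0
        u = np.cross(d_inc, helper)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(d_inc, u)
        # scattered directions: (chunk, n_cos, n_phi, 3)
        dirs = (
            nodes[None, :, None, None] * d_inc[:, None, None, :]
            + sin_w[None, :, None, None]
            * (
                np.cos(phi)[None, None, :, None] * u[:, None, None, :]
                + np.sin(phi)[None, None, :, None] * v[:, None, None, :]
            )
        )
        dz = dirs[..., 2]
        hit = np.zeros(dz.shape, dtype=bool)
        down = dz < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            for zl in layer_z:
                t = np.where(down, zl / np.where(down, dz, -1.0), -1.0)
                x = t * dirs[..., 0]
                y = t * dirs[..., 1]
                hit |= down & (t > 0) & (np.abs(x) <= h) & (np.abs(y) <= h)
        out[lo : lo + chunk] = (hit.mean(axis=2) * kn[None, :]).sum(axis=1) / kn.sum()
    return out


@dataclass
class SensitivityMap:
    """Per-pixel detection-efficiency weights S_j (flat, row-major)."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_pixels:
            raise ValueError("sensitivity size does not match grid")
        if np.any(self.values <= 0):
            raise ValueError("sensitivity must be strictly positive inside the FOV")


def sensitivity_map(
    grid: ImageGrid,
    det: DetectorSpec,
    e_total: float = 511.0,
    include_absorber: bool = True,
    m_sub: int = 16,
    n_cos: int = 64,
    n_phi: int = 32,
) -> SensitivityMap:
    """Analytic detection-efficiency vector S_j.

    S_j = (solid angle of the Si face from pixel j) x (mean
    Klein–Nishina-weighted absorber acceptance), matching the geometric
    and physical acceptance imposed by the event generator. Set
    include_absorber=False for the scatterer-solid-angle-only variant.
    """
    if grid.plane_distance <= 0:
        raise ValueError("grid must be in front of the detector")
    pts = grid.pixel_centers()
    s = si_solid_angle(pts, det, m_sub)
    if include_absorber:
        s = s * _absorber_acceptance(pts, det, e_total, n_cos, n_phi)
    return SensitivityMap(grid, s)
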