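"""Stochastic origin ensemble (SOE) reconstruction.

Each event's presumed origin is a pixel near its Compton-cone section in
the imaging plane. A Metropolis-type chain sweeps the events in list
order: a new origin is proposed uniformly from the event's candidate
set and accepted with probability

    A = min(1, (rho_new + 1) / rho_old)

where rho_old / rho_new are the origin densities (event counts) at the
current and proposed pixel; the +1 accounts for the event joining the
proposed pixel while it is still counted at its current one. The origin
density itself is the image; a Gaussian post-filter suppresses the
high-frequency noise of the finite ensemble (applied on output only,
never inside the chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from numba import njit

from .events import EventList
from .grid import Image, ImageGrid, normalize
from .physics import ArmModel
from .projection import ConeRecord, ConeSet, cones_from_events

__all__ = ["build_candidates", "soe_acceptance", "SoeChain", "SoeResult", "soe_reconstruct"]

log = logging.getLogger(__name__)

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _candidate_mask(
    apex: np.ndarray, axis: np.ndarray, half_angle: float,
    centers: np.ndarray, band: float,
) -> np.ndarray:
    d = centers - apex
    r = np.linalg.norm(d, axis=1)
    cos_a = np.clip(d @ axis / r, -1.0, 1.0)
    return np.abs(np.degrees(np.arccos(cos_a)) - half_angle) <= band


def build_candidates(cone: ConeRecord, grid: ImageGrid, band: float) -> np.ndarray:
    """Flat pixel indices with angular residual <= band (degrees) of the
    cone surface; empty for cones that miss the field of view."""
    if not cone.valid:
        raise ValueError("kinematically invalid cone")
    return np.flatnonzero(
        _candidate_mask(cone.apex, cone.axis, cone.half_angle, grid.pixel_centers(), band)
    ).astype(np.int64)


def soe_acceptance(density_old: int, density_new: int, plus_one: bool = True) -> float:
    """Metropolis acceptance for moving an event from a pixel of density
    density_old (including the event itself, so >= 1) to one of density
    density_new. plus_one=False selects the literal density-ratio
    alternative reading."""
    if density_old < 1:
        raise ValueError("density_old must be >= 1 (the event occupies its pixel)")
    num = density_new + 1 if plus_one else density_new
    return min(1.0, num / density_old)


@njit(cache=True)
def _sweep(origins, density, cand_idx, cand_ptr, u_choice, u_accept, plus_one):
    n_moved = 0
    for i in range(origins.size):
        lo = cand_ptr[i]
        hi = cand_ptr[i + 1]
        j_new = cand_idx[lo + int(u_choice[i] * (hi - lo))]
        j_old = origins[i]
        if j_new == j_old:
            continue
        if plus_one:
            a = (density[j_new] + 1.0) / density[j_old]
        else:
            a = density[j_new] / density[j_old]
        if u_accept[i] < a:
            origins[i] = j_new
            density[j_old] -= 1
            density[j_new] += 1
            n_moved += 1
    return n_moved


class SoeChain:
    """The origin-ensemble Markov chain, advanced one sweep at a time.

    Events whose candidate set is empty (cone misses the FOV) are
    excluded and logged; density always sums to the number of active
    events (exact integer conservation).
    """

    def __init__(
        self,
        events: EventList,
        grid: ImageGrid,
        arm: ArmModel,
        seed: int = 0,
        band: float | None = None,
        plus_one: bool = True,
        system=None,
    ) -> None:
        from ._kernels import gaussian_row

        self.grid = grid
        self.band = arm.fwhm / 2.0 if band is None else band
        self.plus_one = plus_one

        idx_parts: list[np.ndarray] = []
        ptr = [0]
        active = []
        if (
            system is not None
            and system.cand_idx is not None
            and system.candidate_band == self.band
        ):
            for i in range(system.n_events):
                cand = system.cand_idx[system.cand_ptr[i] : system.cand_ptr[i + 1]]
                if cand.size:
                    idx_parts.append(cand.astype(np.int64))
                    ptr.append(ptr[-1] + cand.size)
                    active.append(i)
        else:
            cones = cones_from_events(events)
            centers = grid.pixel_centers()
            use_fast = arm.gamma == 0.0
            buf_idx = np.empty(grid.n_pixels, dtype=np.int32)
            buf_val = np.empty(grid.n_pixels, dtype=np.float64)
            buf_cand = np.empty(grid.n_pixels, dtype=np.int32)
            for i in range(len(cones)):
                if not cones.valid[i]:
                    continue
                if use_fast:
                    _nr, n_cand = gaussian_row(
                        centers, cones.apex[i], cones.axis[i], cones.half_angle[i],
                        arm.sigma, -1.0, self.band, buf_idx, buf_val, buf_cand,
                    )
                    cand = buf_cand[:n_cand].astype(np.int64)
                else:
                    cand = np.flatnonzero(
                        _candidate_mask(
                            cones.apex[i], cones.axis[i], cones.half_angle[i],
                            centers, self.band,
                        )
                    )
                if cand.size:
                    idx_parts.append(cand)
                    ptr.append(ptr[-1] + cand.size)
                    active.append(i)
        self.active = np.array(active, dtype=np.int64)
        n_excluded = len(events) - self.active.size
        if n_excluded:
            log.info("SOE: excluded %d events with empty candidate sets", n_excluded)
        if not self.active.size:
            raise ValueError("no events with on-FOV candidates")
        self.cand_idx = np.concatenate(idx_parts)
        self.cand_ptr = np.array(ptr, dtype=np.int64)

        self.rng = np.random.default_rng(seed)
        n = self.active.size
        # initial origins: uniform over each event's candidate set
        sizes = np.diff(self.cand_ptr)
        pick = (self.rng.random(n) * sizes).astype(np.int64)
        self.origins = self.cand_idx[self.cand_ptr[:-1] + pick]
        self.density = np.bincount(self.origins, minlength=grid.n_pixels).astype(np.int64)
        self.n_sweeps = 0

    @property
    def n_events(self) -> int:
        return self.active.size

    def sweep(self) -> int:
        """One Metropolis sweep over all events in list order; returns the
        number of accepted moves."""
        n = self.n_events
        u = self.rng.random((2, n))
        moved = _sweep(
            self.origins, self.density, self.cand_idx, self.cand_ptr,
            u[0], u[1], self.plus_one,
        )
        self.n_sweeps += 1
        return moved

    def recount(self) -> np.ndarray:
        """Density recomputed from scratch (oracle for the incremental
        bookkeeping)."""
        return np.bincount(self.origins, minlength=self.grid.n_pixels).astype(np.int64)

    def image(self, post_fwhm: float = 5.0) -> Image:
        """Current density as a normalized image, Gaussian-smoothed with
        the given FWHM in mm (0 disables smoothing)."""
        raster = self.density.reshape(self.grid.shape).astype(float)
        if post_fwhm > 0:
            sigma_pix = post_fwhm / _GAUSS_FWHM / self.grid.pixel
            raster = ndi.gaussian_filter(raster, sigma_pix)
        return normalize(Image(self.grid, raster))


@dataclass
class SoeResult:
    grid: ImageGrid
    images: list[Image] = field(default_factory=list)
    iterations: list[int] = field(default_factory=list)  # sweep count per image
    accepted: list[int] = field(default_factory=list)
    chain: SoeChain | None = None

    @property
    def final(self) -> Image:
        return self.images[-1]


def soe_reconstruct(
    events: EventList,
    grid: ImageGrid,
    arm: ArmModel,
    n_iterations: int,
    seed: int = 0,
    post_fwhm: float = 5.0,
    band: float | None = None,
    plus_one: bool = True,
    record_every: int = 1,
    system=None,
) -> SoeResult:
    """Run the SOE chain for n_iterations sweeps.

    Images are recorded every record_every sweeps (and always after the
    last); with a fixed seed the image sequence is bit-reproducible.
    A ConeSystem built with a matching candidate_band is reused.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    chain = SoeChain(events, grid, arm, seed=seed, band=band, plus_one=plus_one, system=system)
    result = SoeResult(grid, chain=chain)
    for k in range(1, n_iterations + 1):
        result.accepted.append(chain.sweep())
        if k % record_every == 0 or k == n_iterations:
            result.images.append(chain.image(post_fwhm))
            result.iterations.append(k)
    return result
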