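"""List-mode ML-EM / OS-EM and the median-root-prior MRP-EM reconstructors.

The ordered-subset update for subset S_l is multiplicative:

    lambda_j <- lambda_j / S_j * sum_{i in S_l} t_ij / (sum_m t_im lambda_m)

and one full iteration cycles through all L subsets. MRP-EM applies the
median root prior one-step-late: the denominator S_j is multiplied by

    1 + beta * (lambda_j - med(lambda_j)) / med(lambda_j)

where med is the median over an odd k x k mask around pixel j, taken on
the current sub-iteration image. The prior asserts that a pixel's most
probable value is its local median, so locally monotonic structure is
untouched while impulsive noise is penalized. With beta = 0 the factor
is exactly one and MRP-EM reduces to OS-EM; with one subset OS-EM
reduces to ML-EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .events import EventList
from .grid import Image, ImageGrid, normalize
from .physics import ArmModel
from .projection import DEFAULT_CUTOFF_FWHM, ConeSystem, SensitivityMap

__all__ = [
    "EmConfig",
    "EmResult",
    "partition_subsets",
    "median_filter",
    "mlem_reconstruct",
    "osem_reconstruct",
    "mrp_em_reconstruct",
    "listmode_loglikelihood",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmConfig:
    """EM reconstruction parameters.

    mask is the odd median-mask side length in pixels (MRP-EM only);
    beta the prior strength; init either "bp" (backprojection, the
    default) or "uniform". med_eps_rel floors the local median at
    med_eps_rel * max(image) and osl_floor floors the one-step-late
    denominator factor, keeping updates positive in cold regions.
    refresh_median controls whether the median image is recomputed every
    sub-iteration (default) or frozen once per full iteration.
    """

    n_iterations: int = 10
    n_subsets: int = 4
    beta: float = 1.0
    mask: int = 7
    init: str = "bp"
    cutoff_fwhm: float = DEFAULT_CUTOFF_FWHM
    med_eps_rel: float = 1e-12
    osl_floor: float = 0.05
    refresh_median: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.mask < 3 or self.mask % 2 == 0:
            raise ValueError("median mask must be odd and >= 3")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.init not in ("bp", "uniform"):
            raise ValueError("init must be 'bp' or 'uniform'")


@dataclass
class EmResult:
    """Per-iteration reconstructions.

    images are the normalized snapshots after each full iteration; raw
    holds the working (unnormalized) estimates on the same schedule —
    normalization happens on output only and never perturbs the
    iteration. n_skipped counts event updates dropped because their
    forward projection was zero.
    """

    grid: ImageGrid
    images: list[Image] = field(default_factory=list)
    raw: list[np.ndarray] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def final(self) -> Image:
        return self.images[-1]


def partition_subsets(n_events: int, n_subsets: int) -> list[np.ndarray]:
    """Deterministic interleaved partition: subset l = indices == l (mod L)."""
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if n_subsets > n_events:
        raise ValueError("more subsets than events")
    return [np.arange(l, n_events, n_subsets) for l in range(n_subsets)]


def median_filter(values: np.ndarray | Image, mask: int = 7):
    """Median over an odd mask x mask window, edges handled by replication."""
    if mask < 3 or mask % 2 == 0:
        raise ValueError("mask must be odd and >= 3")
    if isinstance(values, Image):
        return Image(
            values.grid, ndi.median_filter(values.values, size=mask, mode="nearest")
        )
    return ndi.median_filter(np.asarray(values, dtype=float), size=mask, mode="nearest")


def listmode_loglikelihood(
    system: ConeSystem, sens: SensitivityMap, lam_flat: np.ndarray
) -> float:
    """List-mode Poisson log-likelihood sum_i log(t_i . lam) - S . lam,
    over events with positive forward projection."""
    fwd = system.forward(lam_flat)
    fwd = fwd[fwd > 0]
    return float(np.log(fwd).sum() - sens.values @ lam_flat)


def _initial(system: ConeSystem, cfg: EmConfig) -> np.ndarray:
    if cfg.init == "uniform":
        return np.ones(system.grid.n_pixels)
    bp = system.backprojection()
    if bp.sum() <= 0:
        raise ValueError("backprojection initial image is empty")
    return bp


def _em_run(
    events: EventList,
    grid: ImageGrid,
    arm: ArmModel,
    sens: SensitivityMap,
    cfg: EmConfig,
    system: ConeSystem | None,
    use_prior: bool,
) -> EmResult:
    from ._kernels import csr_subset_update

    if system is None:
        system = ConeSystem(events, grid, arm, cfg.cutoff_fwhm)
    if sens.grid.n_pixels != grid.n_pixels:
        raise ValueError("sensitivity grid does not match reconstruction grid")
    if np.any(sens.values <= 0):
        raise ValueError("sensitivity must be strictly positive")
    n = system.n_events
    subsets = partition_subsets(n, cfg.n_subsets)
    mat = system.matrix
    s_vec = sens.values
    lam = np.ascontiguousarray(_initial(system, cfg), dtype=float)
    shape = grid.shape
    eps_scale = cfg.med_eps_rel
    acc = np.empty(grid.n_pixels)

    result = EmResult(grid)
    med_flat: np.ndarray | None = None
    for _k in range(cfg.n_iterations):
        if use_prior and not cfg.refresh_median:
            med_flat = median_filter(lam.reshape(shape), cfg.mask).ravel()
        for rows in subsets:
            acc[:] = 0.0
            result.n_skipped += csr_subset_update(
                mat.indptr, mat.indices, mat.data, rows, lam, acc
            )
            if use_prior:
                if cfg.refresh_median:
                    med_flat = median_filter(lam.reshape(shape), cfg.mask).ravel()
                med = np.maximum(med_flat, eps_scale * lam.max())
                factor = 1.0 + cfg.beta * (lam - med_flat) / med
                factor = np.maximum(factor, cfg.osl_floor)
                lam = lam * acc / (s_vec * factor)
            else:
                lam = lam * acc / s_vec
        result.raw.append(lam.copy())
        result.images.append(normalize(Image(grid, lam.reshape(shape))))
    if result.n_skipped:
        log.info("EM: skipped %d zero-forward event updates", result.n_skipped)
    return result


def osem_reconstruct(
    events: EventList,
    grid: ImageGrid,
    arm: ArmModel,
    sens: SensitivityMap,
    cfg: EmConfig,
    system: ConeSystem | None = None,
) -> EmResult:
    """Ordered-subset EM; with cfg.n_subsets = 1 this is exactly ML-EM."""
    return _em_run(events, grid, arm, sens, cfg, system, use_prior=False)


def mlem_reconstruct(
    events: EventList,
    grid: ImageGrid,
    arm: ArmModel,
    sens: SensitivityMap,
    cfg: EmConfig,
    system: ConeSystem | None = None,
) -> EmResult:
    """List-mode ML-EM (single subset)."""
    from dataclasses import replace

    return _em_run(events, grid, arm, sens, replace(cfg, n_subsets=1), system, use_prior=False)


def mrp_em_reconstruct(
    events: EventList,
    grid: ImageGrid,
    arm: ArmModel,
    sens: SensitivityMap,
    cfg: EmConfig,
    system: ConeSystem | None = None,
) -> EmResult:
    """OS-EM with the one-step-late median root prior."""
    return _em_run(events, grid, arm, sens, cfg, system, use_prior=True)
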