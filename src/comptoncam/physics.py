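"""Compton kinematics, the Klein–Nishina angular weight, and the Voigt
angular-uncertainty kernel.

For a photon of energy E1+E2 scattering off a free electron at rest, the
scattering angle theta satisfies

    cos(theta) = 1 - m_e c^2 * E1 / (E2 * (E1 + E2))

with E1 the recoil-electron energy deposited in the scatterer and E2 the
energy deposited in the absorber. Angular uncertainty of the resulting
cone (the ARM, angular resolution measure) is modelled as a Voigt
profile — a Gaussian (width sigma) convolved with a Lorentzian
(half-width gamma).

Angles cross module interfaces in degrees; conversion to radians happens
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import voigt_profile

__all__ = [
    "ELECTRON_MASS_KEV",
    "ArmModel",
    "scatter_angle_from_energies",
    "energies_from_angle",
    "klein_nishina_weight",
    "voigt_kernel",
]

ELECTRON_MASS_KEV = 511.0  # m_e c^2

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class ArmModel:
    """Voigt parameters of the angular resolution measure, in degrees.

    fwhm is derived from (sigma, gamma) through the standard Voigt-width
    approximation f ~ 0.5346 f_L + sqrt(0.2166 f_L^2 + f_G^2) (accurate to
    a few 1e-4 relative).
    """

    sigma: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.gamma < 0:
            raise ValueError("sigma and gamma must be nonnegative")
        if self.sigma == 0 and self.gamma == 0:
            raise ValueError("sigma and gamma cannot both be zero")

    @classmethod
    def from_fwhm(cls, fwhm_deg: float) -> "ArmModel":
        """Pure-Gaussian ARM of the given FWHM (the default when only the
        instrument's quoted FWHM is known)."""
        return cls(sigma=fwhm_deg / _GAUSS_FWHM, gamma=0.0)

    @property
    def fwhm(self) -> float:
        f_l = 2.0 * self.gamma
        f_g = _GAUSS_FWHM * self.sigma
        return 0.5346 * f_l + math.sqrt(0.2166 * f_l * f_l + f_g * f_g)

    def density(self, theta_deg: np.ndarray | float) -> np.ndarray | float:
        """Voigt density (per degree) at angular offset theta_deg.

        Degenerate limits use the analytic Gaussian/Lorentzian forms
        directly (they are exact, and the Gaussian path is much cheaper
        in the reconstruction inner loops).
        """
        theta = np.asarray(theta_deg, dtype=float)
        if self.gamma == 0.0:
            s = self.sigma
            out = np.exp(-0.5 * (theta / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
        elif self.sigma == 0.0:
            g = self.gamma
            out = g / (math.pi * (theta * theta + g * g))
        else:
            out = voigt_profile(theta, self.sigma, self.gamma)
        return out if out.shape else float(out)


def scatter_angle_from_energies(
    e1: np.ndarray | float, e2: np.ndarray | float, *, degrees: bool = True
):
    """Scattering angle from the two deposited energies (keV).

    Returns the angle (degrees by default) where the Compton relation is
    satisfiable and NaN where the energy split is kinematically forbidden
    (|cos theta| > 1, e.g. after energy blur) so callers can drop those
    events rather than fail.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any(e1 <= 0) or np.any(e2 <= 0):
        raise ValueError("energies must be positive")
    cos_t = 1.0 - ELECTRON_MASS_KEV * e1 / (e2 * (e1 + e2))
    with np.errstate(invalid="ignore"):
        theta = np.where(np.abs(cos_t) <= 1.0, np.arccos(np.clip(cos_t, -1.0, 1.0)), np.nan)
    if degrees:
        theta = np.degrees(theta)
    return theta if theta.shape else float(theta)


def energies_from_angle(e_total: float, omega_deg: np.ndarray | float):
    """Split a total photon energy into (E1, E2) for scattering angle omega.

    Inverse of scatter_angle_from_energies: the scattered-photon energy is
    E2 = E / (1 + (E/m_e c^2)(1 - cos omega)), and E1 = E - E2.
    """
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    omega = np.asarray(omega_deg, dtype=float)
    if np.any(omega <= 0) or np.any(omega > 180.0):
        raise ValueError("omega must lie in (0, 180] degrees")
    cos_w = np.cos(np.radians(omega))
    e2 = e_total / (1.0 + (e_total / ELECTRON_MASS_KEV) * (1.0 - cos_w))
    e1 = e_total - e2
    if omega.shape:
        return e1, e2
    return float(e1), float(e2)


def klein_nishina_weight(cos_omega: np.ndarray | float, e_total: float):
    """Klein–Nishina angular weight, normalized to 1 at forward scattering.

    With k = E/(m_e c^2) and r = 1 + k(1 - cos w):

        sigma(cos w) = (1 + cos^2 w)/2 * r^-2 * [1 + k^2 (1-cos w)^2 / ((1+cos^2 w) r)]

    Proportional to the Klein–Nishina differential cross-section in
    cos w; used both to sample scattering angles and to weight the
    Legendre coefficients of the analytic inversion.
    """
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    c = np.asarray(cos_omega, dtype=float)
    if np.any(c < -1.0) or np.any(c > 1.0):
        raise ValueError("cos_omega must lie in [-1, 1]")
    k = e_total / ELECTRON_MASS_KEV
    one_m = 1.0 - c
    r = 1.0 + k * one_m
    half = (1.0 + c * c) / 2.0
    out = half / (r * r) * (1.0 + (k * k * one_m * one_m) / ((1.0 + c * c) * r))
    return out if out.shape else float(out)


def voigt_kernel(theta_deg: np.ndarray | float, arm: ArmModel):
    """ARM kernel density (per degree) at angular offset theta_deg.

    Symmetric, peaked at zero, unit integral over theta in (-inf, inf).
    """
    return arm.density(theta_deg)
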