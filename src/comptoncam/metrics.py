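"""Image-quality metrics: RSS, ZNCC, mutual information, the two-point
resolvability rule, and ROI statistics.

All comparisons are between normalized rasters on the same grid. RSS is
the raw residual sum of squares (small is good); ZNCC the zero-mean
normalized cross-correlation in [-1, 1] (1 is perfect up to a positive
affine map); MI the mutual information of the jointly histogrammed
256-level quantizations, in bits (higher means more shared structure,
insensitive to impulsive noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Image

__all__ = [
    "rss",
    "zncc",
    "mutual_information",
    "two_point_resolved",
    "spatial_resolution",
    "roi_stats",
    "MetricReport",
    "metric_report",
]


def _check_pair(truth: Image, recon: Image) -> tuple[np.ndarray, np.ndarray]:
    if truth.grid.shape != recon.grid.shape or truth.grid.pixel != recon.grid.pixel:
        raise ValueError("images are on different grids")
    return truth.values.ravel(), recon.values.ravel()


def rss(truth: Image, recon: Image) -> float:
    """Residual sum of squares Σ (V_T - V_R)^2 over pixels."""
    t, r = _check_pair(truth, recon)
    d = t - r
    return float(d @ d)


def zncc(truth: Image, recon: Image) -> float:
    """Zero-mean normalized cross-correlation (Pearson r over pixels)."""
    t, r = _check_pair(truth, recon)
    t = t - t.mean()
    r = r - r.mean()
    denom = np.sqrt((t @ t) * (r @ r))
    if denom == 0:
        raise ValueError("ZNCC undefined for a constant image")
    return float(t @ r / denom)


def _quantize(v: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot quantize a constant image")
    q = np.floor((v - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def mutual_information(truth: Image, recon: Image, levels: int = 256) -> float:
    """Mutual information (bits) of the two rasters after independent
    linear min–max quantization to `levels` gray levels."""
    t, r = _check_pair(truth, recon)
    qt = _quantize(t, levels)
    qr = _quantize(r, levels)
    joint = np.zeros((levels, levels))
    np.add.at(joint, (qt, qr), 1.0)
    joint /= joint.sum()
    pt = joint.sum(axis=1)
    pr = joint.sum(axis=0)
    nz = joint > 0
    outer = pt[:, None] * pr[None, :]
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def two_point_resolved(profile: np.ndarray, x_centers: np.ndarray) -> bool:
    """Two sources on y = 0 count as resolved when the maxima over x < 0
    and x > 0 both strictly exceed the profile value at x = 0 (mean of
    the two central samples when no sample sits exactly at zero)."""
    profile = np.asarray(profile, dtype=float)
    x = np.asarray(x_centers, dtype=float)
    if profile.shape != x.shape:
        raise ValueError("profile and x_centers must have the same length")
    at_zero = np.isclose(x, 0.0)
    if at_zero.any():
        center = float(profile[at_zero][0])
    else:
        right = int(np.searchsorted(x, 0.0))
        center = 0.5 * (profile[right - 1] + profile[right])
    left_max = profile[x < 0].max()
    right_max = profile[x > 0].max()
    return bool(left_max > center and right_max > center)


def spatial_resolution(resolved: dict[float, bool]) -> float:
    """Smallest separation (mm) flagged resolved; +inf if none is
    (reported as "> max separation")."""
    hits = [sep for sep, ok in resolved.items() if ok]
    return min(hits) if hits else float("inf")


def roi_stats(image: Image, masks: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Per-region mean and coefficient of variation (population SD / mean).

    CV is NaN for zero-mean regions; empty masks raise.
    """
    out: dict[str, dict[str, float]] = {}
    for name, mask in masks.items():
        if mask.shape != image.grid.shape:
            raise ValueError(f"mask {name!r} does not match the image grid")
        vals = image.values[mask]
        if vals.size == 0:
            raise ValueError(f"mask {name!r} is empty")
        mean = float(vals.mean())
        cv = float(vals.std() / mean) if mean != 0 else float("nan")
        out[name] = {"mean": mean, "cv": cv, "n_pixels": int(vals.size)}
    return out


@dataclass
class MetricReport:
    rss: float
    zncc: float
    mi: float
    roi: dict[str, dict[str, float]] | None = None


def metric_report(
    truth: Image,
    recon: Image,
    masks: dict[str, np.ndarray] | None = None,
    levels: int = 256,
) -> MetricReport:
    """RSS/ZNCC/MI (and optional ROI statistics) for one reconstruction."""
    return MetricReport(
        rss=rss(truth, recon),
        zncc=zncc(truth, recon),
        mi=mutual_information(truth, recon, levels),
        roi=roi_stats(recon, masks) if masks else None,
    )
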