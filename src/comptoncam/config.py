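"""Declarative YAML configuration for detector, grid, ARM, and
per-algorithm parameters.

A config file is a single mapping with optional sections; unknown keys
raise. Example::

    grid: {plane_distance: 100, fov_x: 300, fov_y: 300, pixel: 1}
    detector: {active_extent: 32, n_strips: 128}
    arm: {fwhm_deg: 4.9}          # or sigma_deg / gamma_deg
    em: {n_iterations: 20, n_subsets: 4, beta: 1, mask: 7}
    simulate: {n_events: 23648, seed: 0, mode: detector}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .em import EmConfig
from .events import DetectorSpec
from .grid import ImageGrid
from .physics import ArmModel
from .simulate import SimConfig

__all__ = ["load_config", "arm_from_config", "grid_from_config",
           "detector_from_config", "em_from_config", "sim_from_config"]

_SECTIONS = {"grid", "detector", "arm", "em", "simulate", "soe", "analytic"}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def arm_from_config(cfg: dict) -> ArmModel:
    sec = cfg.get("arm", {})
    if "sigma_deg" in sec or "gamma_deg" in sec:
        return ArmModel(sigma=sec.get("sigma_deg", 0.0), gamma=sec.get("gamma_deg", 0.0))
    return ArmModel.from_fwhm(sec.get("fwhm_deg", 4.9))


def grid_from_config(cfg: dict) -> ImageGrid:
    return ImageGrid(**cfg.get("grid", {}))


def detector_from_config(cfg: dict) -> DetectorSpec:
    return DetectorSpec(**cfg.get("detector", {}))


def em_from_config(cfg: dict) -> EmConfig:
    return EmConfig(**cfg.get("em", {}))


def sim_from_config(cfg: dict, n_events: int | None = None) -> SimConfig:
    sec = dict(cfg.get("simulate", {}))
    if n_events is not None:
        sec["n_events"] = n_events
    if "window" in sec:
        sec["window"] = tuple(sec["window"])
    return SimConfig(**sec)
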