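"""Shared fixtures.

Heavy study-scale fixtures (the ellipsoid benchmark and the two-point
resolution study) are session-scoped so the Fig-5-shape, quantification
and resolution-ordering tests all reuse one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from comptoncam import ArmModel, ImageGrid
from comptoncam.benchmark import (
    BenchmarkSpec,
    run_ellipsoid_benchmark,
    run_resolution_study,
)
from comptoncam.events import DetectorSpec
from comptoncam.phantoms import two_point_phantom
from comptoncam.projection import ConeSystem, sensitivity_map
from comptoncam.simulate import SimConfig, simulate_events


@pytest.fixture(scope="session")
def arm() -> ArmModel:
    return ArmModel.from_fwhm(4.9)


@pytest.fixture(scope="session")
def det() -> DetectorSpec:
    return DetectorSpec()


@pytest.fixture(scope="session")
def small_grid() -> ImageGrid:
    """41 x 41 mm, 1 mm pixels — cheap grid for unit tests."""
    return ImageGrid(plane_distance=100.0, fov_x=41.0, fov_y=41.0, pixel=1.0)


@pytest.fixture(scope="session")
def twopoint_grid() -> ImageGrid:
    """The two-point benchmark grid (odd extent, integer pixel centres)."""
    return ImageGrid(plane_distance=100.0, fov_x=101.0, fov_y=101.0, pixel=1.0)


@pytest.fixture(scope="session")
def twopoint_2k(twopoint_grid, arm, det):
    """Seeded 2000-event ideal-cone two-point dataset with its cached
    rows and sensitivity, shared by the algorithm-identity and
    likelihood tests."""
    phantom = two_point_phantom(10.0, twopoint_grid)
    events = simulate_events(
        phantom, det, SimConfig(2000, seed=0, mode="ideal-cone"), arm
    )
    system = ConeSystem(events, twopoint_grid, arm)
    sens = sensitivity_map(twopoint_grid, det)
    return {"events": events, "grid": twopoint_grid, "arm": arm, "det": det,
            "system": system, "sens": sens, "phantom": phantom}


@pytest.fixture(scope="session")
def ellipsoid_result():
    """Full ellipsoid study at the default conditions (23 648
    detector-mode events, OS-EM/MRP-EM to 50 iterations, SOE to 500)."""
    return run_ellipsoid_benchmark(BenchmarkSpec(seed=0))


@pytest.fixture(scope="session")
def resolution_result():
    """Two-point resolution study (16 000 ideal-cone events per
    separation) for BP, OS-EM and MRP-EM."""
    spec = BenchmarkSpec(
        phantom="two-point", n_events=16000, mode="ideal-cone", seed=0,
        algorithms=("bp", "osem", "mrpem"),
    )
    return run_resolution_study(spec)
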