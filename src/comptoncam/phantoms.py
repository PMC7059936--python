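"""Mathematical phantoms: two point sources and a hot/cold-spot ellipsoid.

Activities are relative concentrations on the imaging-plane grid. The
ellipsoid phantom is a large ellipse (LE, concentration 1) containing a
circular hot spot (HS, concentration 3.5, i.e. 3.5x the LE level), two
circular cold spots (CS1, CS2, zero), embedded in a zero background
(BG). Region masks are disjoint and partition the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Image, ImageGrid, normalize

__all__ = ["Phantom", "two_point_phantom", "point_phantom", "ellipsoid_phantom",
           "EllipsoidParams"]

HS_TO_LE_RATIO = 3.5


@dataclass
class Phantom:
    """Activity raster plus (optional) labelled region masks."""

    grid: ImageGrid
    activity: np.ndarray  # (nx, ny), relative concentration
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != self.grid.shape:
            raise ValueError("activity shape does not match grid")
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")

    def truth_image(self) -> Image:
        """Normalized activity raster (the reference for image metrics)."""
        return normalize(Image(self.grid, self.activity))


def _nearest_center(centers: np.ndarray, target: float, pixel: float) -> int:
    i = int(np.argmin(np.abs(centers - target)))
    if abs(centers[i] - target) > 1e-9 * max(1.0, pixel):
        raise ValueError(
            f"position {target} mm is not representable on the grid "
            f"(nearest pixel centre {centers[i]} mm)"
        )
    return i


def point_phantom(grid: ImageGrid, x: float = 0.0, y: float = 0.0) -> Phantom:
    """Single point source at a pixel centre (default: nearest to origin)."""
    xc, yc = grid.x_centers(), grid.y_centers()
    i = int(np.argmin(np.abs(xc - x)))
    j = int(np.argmin(np.abs(yc - y)))
    act = np.zeros(grid.shape)
    act[i, j] = 1.0
    return Phantom(grid, act)


def two_point_phantom(separation: float, grid: ImageGrid) -> Phantom:
    """Two equal point sources on y = 0 at x = +/- separation/2.

    Both source positions must fall exactly on pixel centres; otherwise a
    ValueError is raised (the resolvability analysis depends on symmetric
    placement about x = 0).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    xc = grid.x_centers()
    yc = grid.y_centers()
    # the row nearest y = 0 (exactly 0 on odd-extent grids, +-pixel/2
    # on even-extent ones)
    j = int(np.argmin(np.abs(yc)))
    if abs(yc[j]) > grid.pixel / 2:
        raise ValueError("grid has no pixel-centre row near y = 0")
    i_left = _nearest_center(xc, -separation / 2.0, grid.pixel)
    i_right = _nearest_center(xc, +separation / 2.0, grid.pixel)
    if i_left == i_right:
        raise ValueError("separation too small: both sources fall in one pixel")
    act = np.zeros(grid.shape)
    act[i_left, j] = 1.0
    act[i_right, j] = 1.0
    return Phantom(grid, act)


@dataclass(frozen=True)
class EllipsoidParams:
    """Geometry of the hot/cold-spot ellipse phantom (mm).

    Defaults approximate the published layout: a 90 x 55 mm semi-axis
    ellipse with a 15 mm hot spot at upper left and 10 mm / 7 mm cold
    spots; only the topology and the 3.5:1 hot-spot contrast are
    normative, the dimensions are configurable.
    """

    le_semi_x: float = 90.0
    le_semi_y: float = 55.0
    hs_center: tuple[float, float] = (-40.0, 25.0)
    hs_radius: float = 15.0
    cs1_center: tuple[float, float] = (35.0, 15.0)
    cs1_radius: float = 10.0
    cs2_center: tuple[float, float] = (10.0, -30.0)
    cs2_radius: float = 7.0


def _disk_mask(grid: ImageGrid, center: tuple[float, float], radius: float) -> np.ndarray:
    xx, yy = np.meshgrid(grid.x_centers(), grid.y_centers(), indexing="ij")
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def ellipsoid_phantom(
    grid: ImageGrid, params: EllipsoidParams | None = None
) -> Phantom:
    """Hot/cold-spot ellipse phantom with regions {HS, LE, CS1, CS2, BG}.

    Concentrations: LE = 1, HS = 3.5, CS1 = CS2 = BG = 0. The three spots
    must lie fully inside the ellipse and must not overlap each other.
    """
    p = params or EllipsoidParams()
    xx, yy = np.meshgrid(grid.x_centers(), grid.y_centers(), indexing="ij")
    ellipse = (xx / p.le_semi_x) ** 2 + (yy / p.le_semi_y) ** 2 <= 1.0

    spots = {
        "HS": (p.hs_center, p.hs_radius),
        "CS1": (p.cs1_center, p.cs1_radius),
        "CS2": (p.cs2_center, p.cs2_radius),
    }
    masks: dict[str, np.ndarray] = {}
    for name, (c, r) in spots.items():
        # containment check on the circle boundary, not just the centre
        phi = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
        bx = c[0] + r * np.cos(phi)
        by = c[1] + r * np.sin(phi)
        if np.any((bx / p.le_semi_x) ** 2 + (by / p.le_semi_y) ** 2 > 1.0):
            raise ValueError(f"{name} is not fully inside the large ellipse")
        masks[name] = _disk_mask(grid, c, r)

    for a, b in [("HS", "CS1"), ("HS", "CS2"), ("CS1", "CS2")]:
        if np.any(masks[a] & masks[b]):
            raise ValueError(f"regions {a} and {b} overlap")

    le = ellipse & ~(masks["HS"] | masks["CS1"] | masks["CS2"])
    bg = ~ellipse
    regions = {"HS": masks["HS"], "LE": le, "CS1": masks["CS1"], "CS2": masks["CS2"], "BG": bg}

    act = np.zeros(grid.shape)
    act[le] = 1.0
    act[masks["HS"]] = HS_TO_LE_RATIO
    return Phantom(grid, act, regions)
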