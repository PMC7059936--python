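"""Reconstruction grid and image containers.

The imaging plane is parallel to the detector planes. Coordinate frame
convention (the instrument itself fixes no world frame, so this package
adopts one): origin at the centre of the Si scatterer, +z toward the
source, imaging plane at z = +plane_distance, absorber layers at z < 0.

Images are rasters of nonnegative activity attributed to pixel-centre
points; reconstructed images are compared after normalization by the sum
of pixel values, so absolute scales are immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ImageGrid", "Image", "normalize", "pixel_center", "read_image", "write_image"]


@dataclass(frozen=True)
class ImageGrid:
    """A planar reconstruction raster at z = plane_distance.

    Pixel (i, j) has centre (-fov_x/2 + (i+0.5)*pixel, -fov_y/2 + (j+0.5)*pixel,
    plane_distance); i indexes x, j indexes y, 0-based, row-major.
    """

    plane_distance: float = 100.0  # mm
    fov_x: float = 300.0  # mm
    fov_y: float = 300.0  # mm
    pixel: float = 1.0  # mm

    def __post_init__(self) -> None:
        for name in ("plane_distance", "fov_x", "fov_y", "pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for fov in (self.fov_x, self.fov_y):
            n = fov / self.pixel
            if abs(n - round(n)) > 1e-9:
                raise ValueError("fov must be an exact multiple of the pixel size")

    @property
    def nx(self) -> int:
        return round(self.fov_x / self.pixel)

    @property
    def ny(self) -> int:
        return round(self.fov_y / self.pixel)

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def x_centers(self) -> np.ndarray:
        return -self.fov_x / 2.0 + (np.arange(self.nx) + 0.5) * self.pixel

    def y_centers(self) -> np.ndarray:
        return -self.fov_y / 2.0 + (np.arange(self.ny) + 0.5) * self.pixel

    def pixel_centers(self) -> np.ndarray:
        """(nx*ny, 3) array of pixel-centre points, row-major in (i, j)."""
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers(), indexing="ij")
        out = np.empty((self.n_pixels, 3))
        out[:, 0] = xx.ravel()
        out[:, 1] = yy.ravel()
        out[:, 2] = self.plane_distance
        return out

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (i, j) containing the point (x, y); raises if off-grid."""
        i = int(np.floor((x + self.fov_x / 2.0) / self.pixel))
        j = int(np.floor((y + self.fov_y / 2.0) / self.pixel))
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise ValueError(f"point ({x}, {y}) lies outside the field of view")
        return i, j


def pixel_center(grid: ImageGrid, i: int, j: int) -> np.ndarray:
    """3-vector (mm) of the centre of pixel (i, j)."""
    if not (0 <= i < grid.nx and 0 <= j < grid.ny):
        raise IndexError(f"pixel index ({i}, {j}) out of range for {grid.nx}x{grid.ny} grid")
    x = -grid.fov_x / 2.0 + (i + 0.5) * grid.pixel
    y = -grid.fov_y / 2.0 + (j + 0.5) * grid.pixel
    return np.array([x, y, grid.plane_distance])


@dataclass
class Image:
    """Nonnegative raster on an ImageGrid, shape (nx, ny)."""

    grid: ImageGrid
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("image values must be nonnegative")

    def total(self) -> float:
        return float(self.values.sum())

    def profile_y0(self) -> np.ndarray:
        """Line profile along y = 0 (central row; mean of the two central
        rows when ny is even)."""
        ny = self.grid.ny
        if ny % 2:
            return self.values[:, ny // 2].copy()
        return 0.5 * (self.values[:, ny // 2 - 1] + self.values[:, ny // 2])


def normalize(image: Image) -> Image:
    """Divide by the sum of pixel values so the raster sums to one."""
    s = image.values.sum()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero image")
    return Image(image.grid, image.values / s, normalized=True)


# ---------------------------------------------------------------------------
# image file I/O: flat text raster + JSON sidecar with grid metadata

def write_image(image: Image, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, image.values, fmt="%.17g")
    meta = {
        "plane_distance": image.grid.plane_distance,
        "fov_x": image.grid.fov_x,
        "fov_y": image.grid.fov_y,
        "pixel": image.grid.pixel,
        "nx": image.grid.nx,
        "ny": image.grid.ny,
        "normalized": image.normalized,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> Image:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = ImageGrid(
        plane_distance=meta["plane_distance"],
        fov_x=meta["fov_x"],
        fov_y=meta["fov_y"],
        pixel=meta["pixel"],
    )
    values = np.loadtxt(path).reshape(grid.shape)
    return Image(grid, values, normalized=meta["normalized"])


def export_png(image: Image, path: str | Path) -> None:
    """8-bit grayscale export for visual inspection only (lossy)."""
    from PIL import Image as PILImage

    v = image.values
    scaled = np.zeros_like(v) if v.max() <= 0 else v / v.max()
    arr = (255 * scaled.T[::-1]).astype(np.uint8)  # y up, x right
    PILImage.fromarray(arr, mode="L").save(Path(path))
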