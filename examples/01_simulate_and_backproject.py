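"""Simulate a point-source acquisition and backproject it.

Generates 5000 detector-mode coincidences from a 511 keV point source
100 mm in front of the Si/CdTe camera, reconstructs by simple
backprojection (inverse-square-weighted Voigt cones), and reports where
the activity lands and how sharp the angular response is.
"""

import numpy as np

from comptoncam import ArmModel, ImageGrid, backproject
from comptoncam.events import DetectorSpec
from comptoncam.phantoms import point_phantom
from comptoncam.projection import cones_from_events
from comptoncam.simulate import SimConfig, simulate_events

grid = ImageGrid(fov_x=101.0, fov_y=101.0, pixel=1.0)  # 1 mm pixels, z = 100 mm
arm = ArmModel.from_fwhm(4.9)  # angular resolution measure, degrees
det = DetectorSpec()

phantom = point_phantom(grid, x=10.0, y=-5.0)
events = simulate_events(phantom, det, SimConfig(5000, seed=1), arm)
print(f"simulated {len(events)} windowed events; "
      f"mean E1+E2 = {events.e_sum.mean():.1f} keV")

img = backproject(events, grid, arm)
i, j = np.unravel_index(np.argmax(img.values), img.values.shape)
print(f"backprojection peak at ({grid.x_centers()[i]:+.0f}, {grid.y_centers()[j]:+.0f}) mm "
      f"(truth: (+10, -5) mm)")

# empirical ARM: signed angular distance of the true source from each cone
cones = cones_from_events(events)
ok = cones.valid
d = np.array([10.0, -5.0, 100.0]) - cones.apex[ok]
alpha = np.degrees(np.arccos(np.clip(
    np.einsum("ij,ij->i", d, cones.axis[ok]) / np.linalg.norm(d, axis=1), -1, 1)))
resid = alpha - cones.half_angle[ok]
print(f"median |angular residual| = {np.median(np.abs(resid)):.2f} deg "
      f"(configured ARM FWHM {arm.fwhm:.1f} deg)")
# The peak should sit on the true source and the residual scale should
# match the configured angular blur.
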