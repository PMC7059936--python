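"""OS-EM against MRP-EM on a reduced hot/cold-spot phantom.

Runs both reconstructors for 20 iterations on 6000 events from the
ellipse phantom (hot spot at 3.5x the background ellipse, two cold
spots) and prints the residual sum of squares (RSS) against the true
activity map at several iteration counts. OS-EM attains its best RSS
early and then degrades as noise amplifies; the median root prior keeps
MRP-EM near its optimum.
"""

import numpy as np

from comptoncam import ArmModel, ImageGrid
from comptoncam.em import EmConfig, mrp_em_reconstruct, osem_reconstruct
from comptoncam.events import DetectorSpec
from comptoncam.metrics import rss
from comptoncam.phantoms import ellipsoid_phantom
from comptoncam.projection import ConeSystem, sensitivity_map
from comptoncam.simulate import SimConfig, simulate_events

grid = ImageGrid(fov_x=201.0, fov_y=131.0, pixel=1.0)
arm = ArmModel.from_fwhm(4.9)
det = DetectorSpec()
phantom = ellipsoid_phantom(grid)
truth = phantom.truth_image()

events = simulate_events(phantom, det, SimConfig(6000, seed=3), arm)
system = ConeSystem(events, grid, arm, cutoff_fwhm=3.0)  # cached cone rows
sens = sensitivity_map(grid, det)

cfg = EmConfig(n_iterations=20, n_subsets=4, beta=1.0, mask=7, cutoff_fwhm=3.0)
osem = osem_reconstruct(events, grid, arm, sens, cfg, system=system)
mrp = mrp_em_reconstruct(events, grid, arm, sens, cfg, system=system)

print("iteration   RSS(OS-EM)   RSS(MRP-EM)")
for k in (1, 3, 5, 10, 20):
    print(f"{k:9d}   {rss(truth, osem.images[k-1]):.3e}    {rss(truth, mrp.images[k-1]):.3e}")
# Smaller RSS = closer to the true activity map. Watch OS-EM reach a
# minimum and climb again while MRP-EM stays flat near its best value.
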