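"""Stochastic origin ensemble and analytic inversion of the same data.

Reconstructs 8000 ideal-cone events from two point sources 12 mm apart
with (a) the SOE Markov chain (each event's presumed origin hops along
its cone, accepted by a density ratio) and (b) the Klein–Nishina-
weighted Legendre-series inversion of the binned cone-axis projections.
Prints whether each method separates the pair.
"""

import numpy as np

from comptoncam import ArmModel
from comptoncam.analytic import analytic_reconstruct
from comptoncam.benchmark import two_point_grid_for
from comptoncam.events import DetectorSpec
from comptoncam.metrics import two_point_resolved
from comptoncam.phantoms import two_point_phantom
from comptoncam.simulate import SimConfig, simulate_events
from comptoncam.soe import soe_reconstruct

sep = 12.0
grid = two_point_grid_for(sep)
arm = ArmModel.from_fwhm(4.9)
det = DetectorSpec()
phantom = two_point_phantom(sep, grid)
events = simulate_events(phantom, det, SimConfig(8000, seed=4, mode="ideal-cone"), arm)

soe = soe_reconstruct(events, grid, arm, n_iterations=200, seed=5,
                      post_fwhm=5.0, record_every=10**9)
print(f"SOE: {soe.chain.n_events} origins after 200 sweeps, "
      f"density sum = {soe.chain.density.sum()}")

ana = analytic_reconstruct(events, grid, arm=arm)

x = grid.x_centers()
for name, img in (("SOE(200)", soe.final), ("analytic", ana)):
    prof = img.profile_y0()
    flag = "resolved" if two_point_resolved(prof, x) else "not resolved"
    peak = x[np.argmax(prof)]
    print(f"{name:10s}: peak at x = {peak:+.0f} mm, pair at +-{sep/2:.0f} mm -> {flag}")
# "resolved" means both half-plane maxima of the y = 0 profile exceed
# the value at x = 0 — the study's two-point resolvability rule.
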