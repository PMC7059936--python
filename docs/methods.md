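# Methods

This note records the models, conventions and numerical choices behind
`comptoncam`, in the order data flows through the package.

## Geometry and conventions

The instrument is a single 32 × 32 mm² double-sided Si strip detector
(128 strips per side, 0.25 mm pitch, 500 µm thick) backed by three
CdTe layers of the same area (750 µm thick, 4 mm gaps between facing
surfaces). No world frame is standard for such cameras, so the package
fixes one: origin at the Si centre, +z toward the source, imaging plane
parallel to the detectors at z = +100 mm, absorber layer centres at
z = −4.625, −9.375, −14.125 mm. Images are rasters whose pixel value is
the activity attributed to the pixel-centre point; pixel (i, j) of a
grid with extent `fov` and pitch `p` has centre −fov/2 + (i + 0.5)·p.
Reconstructions are compared after normalization by the sum of pixel
values, so all image scales are relative.

Angles cross interfaces in degrees; energies in keV; lengths in mm.

## Angular uncertainty (ARM)

The angular resolution measure — the distribution of the angular
distance between the true source direction and the nearest cone-surface
direction — is modelled as a Voigt profile with Gaussian width σ and
Lorentzian half-width γ. When only the instrument's quoted FWHM is
known (4.9° at 511 keV for this camera), the default is pure Gaussian
with σ = FWHM/2.35482; σ and γ can be set individually when a
point-source calibration is available. The Voigt density is evaluated
by `scipy.special.voigt_profile`, with the exact Gaussian/Lorentzian
forms substituted in the degenerate limits (identical analytically,
and the Gaussian path is what the reconstruction inner loops use).

## Synthetic event generator

The generator replaces a full Monte Carlo detector simulation with a
parametric chain whose every stage is testable:

1. emission pixel sampled ∝ activity; the emission point is the pixel
   centre;
2. scatter point: uniform draws over the Si volume accepted with
   probability cos³θ_inc, which makes the per-pixel detection
   probability proportional to the Si solid angle and the conditional
   scatter-point density the solid-angle measure — i.e. the geometry
   the analytic sensitivity map (below) assumes;
3. true scattering angle ω sampled from the Klein–Nishina angular
   weight (normalized to 1 at forward scattering, its maximum, so
   uniform-proposal rejection is exact);
4. deposited energies derived from an ARM-perturbed angle
   ω + δ, δ ~ Voigt(σ, γ): an energy–angle decorrelation that stands in
   for Doppler broadening and intrinsic resolution and realizes the
   configured ARM in the reconstructed cones. E1 + E2 = E_source is
   preserved exactly at this stage;
5. the scattered ray (true ω, uniform azimuth) is propagated into the
   CdTe stack; events that miss all three layers are discarded, which
   imposes the Klein–Nishina-weighted absorber acceptance;
6. both interaction points are quantized to strip centres; additive
   Gaussian noise (default σ = 1.6 keV per detector, consistent with a
   3.8 keV FWHM resolution) is applied to E1 and E2;
7. a photo-peak window on E1+E2 (default 501–521 keV) selects fully
   absorbed events. Generation repeats until the requested count
   survives the window.

The realized ARM of this chain is ~5.2° FWHM: the configured 4.9° Voigt
perturbation convolved with the small strip-quantization and
energy-noise contributions. An `ideal-cone` mode bypasses the detector:
each event is an exact cone through the true source whose recorded
half-angle carries one ARM draw — useful for isolating reconstruction
behaviour from detector effects.

Not modelled: photon attenuation and scatter in the object, accidental
coincidences, detector dead time, depth-of-interaction blur, and the
energy dependence of the CdTe response. Consequently, passing tests
demonstrate algorithmic correctness and behaviour under the stated blur
model, not performance on a physical camera.

## Transition weights and the cached system

t_ij = |D|⁻² V(θ_ij) with D the apex→pixel-centre vector in mm (the
inverse square corrects the near-field distance effect; the mm⁻² scale
is harmless because images are normalized). Rows are truncated at
5 ARM FWHM of angular residual by default (configurable); the benchmark
workflows use 3 FWHM ≈ 7 Gaussian σ, where the discarded kernel mass
(~10⁻¹¹ of the peak) is far below the float32 precision of the cached
rows. `ConeSystem` caches all rows of an event list as one CSR matrix
(float32 values, int32 indices, ~2 GB for the ellipsoid benchmark) and
is shared by BP, both EM variants and the SOE candidate sets;
kinematically forbidden events (|cos θ| > 1 after blur, as in real
photo-peak data) are kept as all-zero rows, flagged, and skipped by
every consumer. All accumulations over the float32 rows (forward
projections, backprojection, EM updates, log-likelihood) run in
float64.

## Sensitivity map

S_j = Ω_j · A_j: the solid angle Ω_j of the Si face from pixel j
(midpoint quadrature over an m×m subdivision of the face, default
m = 16) times the Klein–Nishina-weighted probability A_j that the
scattered ray from the scatterer hits any absorber layer
(Gauss–Legendre in cos ω, default 64 nodes, × 32 uniform azimuths).
This matches the acceptance imposed by the generator: the detected-
emission marginal of the simulator equals activity × S to ~1% on a
uniform phantom. A scatterer-solid-angle-only variant is available via
`include_absorber=False` for data whose absorber acceptance is not
modelled.

## EM reconstructors

List-mode OS-EM uses the multiplicative subset update with the
index-modulo-L subset partition (deterministic, balanced; event order
is therefore part of the data contract and file I/O preserves it). The
initial image is the backprojection by default (uniform optional); the
initial scale is irrelevant because one multiplicative update absorbs
it. Per-iteration snapshots are of the working (unnormalized) estimate;
normalization happens on output only. Events whose forward projection
is zero are skipped in that update and counted.

MRP-EM multiplies the denominator S_j one-step-late by
1 + β(λ_j − med λ_j)/med λ_j with β = 1 and a 7×7 median mask by
default. The median image is recomputed each sub-iteration (a flag
freezes it per full iteration; in the hot/cold-spot study the frozen
variant is strictly worse on every measure, supporting the refresh
reading). Guards: the median in the denominator is floored at
10⁻¹² × max(λ) and the whole one-step-late factor at 0.05, keeping
updates positive in cold regions; both thresholds are configurable.
Median filtering is `scipy.ndimage.median_filter` with edge
replication, chosen over zero padding to avoid darkening the FOV rim.
With β = 0 the factor is exactly 1 and MRP-EM is bit-identical to
OS-EM; with one subset OS-EM is ML-EM — both identities are enforced in
the test suite, as is the monotonicity of the list-mode Poisson
log-likelihood Σ_i log(t_i·λ) − S·λ under ML-EM.

## SOE

Each event's presumed origin is initialized uniformly on its candidate
set — the pixels within half an ARM FWHM of angular residual of its
cone (band configurable). One sweep visits events in list order,
proposes a uniform candidate, and accepts with
A = min(1, (ρ_new + 1)/ρ_old), where ρ are single-pixel origin counts:
the +1 counts the event joining the proposed pixel while it is still
counted at its current one (the alternative plain-ratio reading is a
flag; a wider density neighbourhood is not provided because the
single-pixel density is the dial the acceptance ratio actually uses).
Density bookkeeping is incremental and integer-exact; a recount oracle
checks it in the tests. Images are the density raster smoothed by a
Gaussian of 5 mm FWHM (output only, never inside the chain) and
normalized. One seeded generator drives initialization and all
proposals, so runs are bit-reproducible.

## Analytic inversion

Cone axes of events with half-angle in [ω₁, ω₂] (defaults 5°–90°) are
binned on an equal-area hemisphere grid (50 rings × 200 azimuths) and
16 equal-width bands in cos ω, normalized per cell solid angle and band
width. The inversion kernel is the truncated Legendre series

    k⁻¹(t, p; ω) = Σ_n (2n+1)/(4π) · a_n · P_n(cos ω) P_n(t·p) / H_n,
    H_n = ∫ σ_KN(cos ω) P_n(cos ω)² dcos ω,

with H_n by Gauss–Legendre quadrature (order ≥ 2 n_max) and Gaussian
apodization a_n = exp(−n(n+1)σ_b²/2). The apodization width is matched
to the angular resolution as σ_b = ARM FWHM in radians: with the
narrower reading (Gaussian σ) the coefficients (2n+1)²/H_n still grow
at the default truncation n_max = 60 and the series is visibly
unconverged, while the FWHM reading converges well inside n_max —
structure finer than the resolution limit is unrecoverable regardless.
Reconstruction evaluates the series through a 4096-point lookup table
per band (linear interpolation in cos(t·p), ~10⁻⁶ relative error),
floors negative ringing at zero, and normalizes. The method is
intrinsically far-field: apexes are collapsed to the frame origin and
only axis directions enter, a method-inherent approximation at 100 mm
source distance.

## Metrics

RSS, ZNCC and MI compare normalized rasters on the same grid. MI
quantizes each image linearly between its own min and max into 256
levels (per-image, not joint, range) and reports bits (log₂ — the base
only scales values, so absolute MI is comparable only within one
convention). Note the finite-sample bias of MI,
≈ (B−1)²/(2N ln 2) for B levels and N pixels, which is ~0.5 bits at
256 levels on a 10⁵-pixel image: MI differences between algorithms on
the same grid are meaningful, small absolute values are not. ROI
statistics use the population standard deviation. Two point sources
count as resolved when both half-plane maxima of the profile through
the sources exceed the profile value at x = 0 (central-pair mean when
no sample sits at zero); the reported spatial resolution is the
smallest scanned separation that resolves.

## Benchmark workflows and problem sizes

The ellipsoid study uses a 201 × 131 mm FOV at 1 mm pixels (26 331
pixels) — the phantom (ellipse semi-axes 90 × 55 mm, 15 mm hot spot at
3.5:1, 10 and 7 mm cold spots; dimensions configurable, topology and
contrast fixed) plus a ≥ 10 mm background margin. The pixel size is
kept at 1 mm deliberately: the 7×7 median mask and the events-per-pixel
regime are part of the method's operating point, so the field of view,
not the pitch, is the scaled-down axis relative to a full 300 × 300 mm
survey (whose ~10⁹-element row cache would not fit in ordinary memory).
Default 23 648 detector-mode events; OS-EM/MRP-EM curves to 50
iterations, SOE to 500 sweeps (the 10× convention), comparison table at
10/20/200. Evaluation ROIs are the region masks eroded by 3 mm,
emulating ROIs drawn inside each region boundary.

The two-point study uses 16 000 ideal-cone events per separation on
1 mm grids sized so the sources sit exactly on pixel centres: a 101 mm
odd-extent FOV (integer centres, exact x = 0 column) for even
separations and a 102 mm FOV (half-integer centres, central-pair rule)
for odd ones — no single 1 mm grid represents both parities
symmetrically. Separations are scanned upward and the scan stops once
every requested algorithm has resolved.

Under these conditions the qualitative study behaviour reproduces: the
OS-EM RSS curve has an interior minimum (iteration ~4) and degrades
several-fold by iteration 50; MRP-EM stays within a few percent of its
running minimum (typical drift 2.5–3.5%, driven by slow hot-spot/
background redistribution rather than impulse noise); SOE holds its RSS
within ±5% over sweeps 100–200; MRP-EM at 20 iterations recovers the
hot-spot contrast at ~3.1 of the true 3.5 and suppresses the 10 mm cold
spot below half the ellipse level. The 7 mm cold spot sits below the
~8.6 mm spatial blur of a 4.9° ARM at 100 mm, and its ~45-pixel ROI
mean is variance-dominated (0.45–0.75 of the ellipse level across
seeds). Resolution ordering is OS-EM ≤ SOE ≤ BP, MRP-EM — the median
prior trades resolution for stability, as any smoothing prior must.

## Known limitations

- 2D planar reconstruction only; no 3D volumes.
- The generator's blur model is parametric; no microscopic Doppler or
  charge-transport physics.
- The analytic method's far-field approximation biases it at 100 mm.
- Absolute MI values depend on quantization convention (see above).
- The SOE implementation is a single chain; no multi-chain averaging.
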