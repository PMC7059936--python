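# comptoncam

List-mode image reconstruction for Compton cameras, built around a
median-root-prior ordered-subset EM algorithm (MRP-EM) and four
comparators: simple backprojection (BP), list-mode ML-EM/OS-EM, the
stochastic origin ensemble (SOE) Markov chain, and an analytic
spherical-harmonic inversion of the cone transform. A seeded synthetic
event generator stands in for a full Monte Carlo detector simulation,
and an evaluation suite (RSS, ZNCC, mutual information, two-point
resolvability, ROI statistics) closes the loop.

## The problem

A Compton camera images a gamma-ray source distribution without a
mechanical collimator. Each *event* is a coincidence: a Compton scatter
in a Si strip detector (deposited energy E1) followed by absorption in
a CdTe layer (energy E2). Kinematics restrict the photon's origin to a
cone — apex at the scatter position, axis along the reversed scattered
path, half-angle θ from

    cos θ = 1 − m_e c² · E1 / (E2 (E1 + E2)).

Reconstruction means turning a list of such cones into an activity map
λ_j on an imaging plane. The workhorse is list-mode OS-EM,

    λ_j^(k,l+1) = λ_j^(k,l) / S_j · Σ_{i∈S_l} t_ij / Σ_m t_im λ_m^(k,l),

with transition weights t_ij = |D|⁻² V(θ_i; σ, γ) (V a Voigt model of
the angular resolution measure, |D|⁻² the near-field distance
correction) and an analytic sensitivity S_j. OS-EM amplifies noise as
iterations grow, and the optimal stopping point is unknown in practice.
MRP-EM regularizes it one-step-late with a median root prior: the
denominator gains the factor

    1 + β (λ_j − med(λ_j)) / med(λ_j),

where med is the median over a k×k neighbourhood — asserting that each
pixel's most probable value is its local median, which suppresses
impulsive noise while leaving locally monotone structure alone. The
result is reconstruction quality that is robust to the iteration count.

## Worked example

`examples/02_osem_vs_mrpem.py` simulates 6000 events from the
hot/cold-spot ellipse phantom (hot spot at 3.5× the ellipse
concentration, two cold spots at zero) and reconstructs with both EM
variants at β = 1, 7×7 median mask, 4 subsets:

```
iteration   RSS(OS-EM)   RSS(MRP-EM)
        1   1.481e-05    1.495e-05
        3   1.342e-05    1.172e-05
        5   1.730e-05    1.169e-05
       10   3.084e-05    1.242e-05
       20   6.153e-05    1.288e-05
```

RSS is the summed squared difference from the true (normalized)
activity map, so smaller is better. OS-EM is best near iteration 3 and
then degrades by 4× as it starts fitting Poisson noise; MRP-EM reaches
the same optimum and stays there — the property the algorithm is for.
The other examples cover simulation + backprojection, SOE + the
analytic method, and the two-point resolution scan; each prints a
one-line interpretation of its numbers.

A thin CLI wraps the same library calls:

```
comptoncam simulate --phantom ellipsoid --n-events 23648 --seed 1 --out ev.tsv
comptoncam reconstruct --algo mrpem --events ev.tsv --iters 20 --out recon.txt
comptoncam evaluate --truth truth.txt recon.txt
comptoncam benchmark --phantom ellipsoid --out-dir bench/
```

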