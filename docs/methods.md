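# Methods

## Scope and model

`photonbench` simulates steady-state photon transport in non-absorbing
media — an infinite homogeneous medium and a laterally infinite layered
slab — and verifies the simulator against exact solutions of the radiative
transfer equation (RTE).  Verification is statistical: a Monte Carlo
estimate with standard error SE is compared with an exact value by the
normalized deviation t = (estimate − exact)/SE and a two-sided one-sample
t-test.  The package therefore contains three things: the transport
simulators, the closed-form reference values, and the test harness that
connects them.

Absorption is deliberately absent.  Trajectories do not depend on the
absorption coefficient; a code verified on its trajectories and partial
path lengths supports absorption weighting by the microscopic
Beer–Lambert factor exp(−μa·path) without further transport changes.
Absorption weighting, Mie phase functions, polarization and non-slab
geometries are out of scope.

## Step 1: infinite-medium coordinate moments

A pencil beam starts at the origin along +z in a medium with scattering
coefficient μs and a rotationally symmetric phase function with moments
g = ⟨cos θ⟩ and g2 = ⟨cos² θ⟩.  For the k-th scattering event the exact
first and second moments of the event coordinates are polynomial in g and
g2; the package implements the full set for orders 1–4, plus for any order

- ⟨z_k⟩ = (1 − g^k)/(μs(1 − g)), whose k→∞ limit is the transport mean
  free path 1/(μs(1−g));
- ⟨d_k²⟩ = 2(k − (k+1)g + g^{k+1})/(μs(1−g))²;
- the path-length moments ⟨l_k^m⟩ = k(k+1)⋯(k+m−1)/μs^m, which are
  independent of the phase function;
- for isotropic scattering the complete set ⟨x_k²⟩ = (2/3)(k−1)/μs²,
  ⟨z_k²⟩ = (2/3)(k+2)/μs², ⟨d_k²⟩ = 2k/μs², with the exact offset
  ⟨z_k²⟩ − ⟨x_k²⟩ = 2/μs² at every order.

Printed-table cross-checks, the identity ⟨z²⟩ + ⟨ρ²⟩ = ⟨d²⟩, and the
reduction to the isotropic forms at (g, g2) = (0, 1/3) jointly pin down
the algebraic form of each coefficient; the implementation writes the
polynomials out explicitly and the test-suite asserts all three
constraints.

The simulator follows every trajectory for exactly `k_max` scattering
events (no termination is possible in a non-absorbing infinite medium), so
each order receives exactly N contributions and no termination bias can
arise.  Tallies are running sums and sums of squares per (order, quantity)
— O(k_max) memory; per-photon data is reduced immediately.  Sampling is
standard: exponential free paths −ln(u)/μs (u = 0 remapped to the smallest
positive uniform), Henyey–Greenstein cosines by the closed-form inverse
CDF, Rayleigh cosines by Cardano's solution of the cubic CDF
μ³ + 3μ + (4 − 8u) = 0 — its discriminant is bounded below by 1, so no
iterative fallback is ever needed — and local-frame rotation with a
degenerate-formula guard when |μz| > 1 − 1e−12.

Reproducibility: photons are processed in fixed blocks of 2^16
trajectories, each driven by its own counter-based Philox generator keyed
on (seed, block index).  A run is therefore bitwise identical to the merge
of its block-aligned sub-ranges, which the suite asserts.

## Step 2: layered slab under Lambertian illumination

For a non-absorbing medium of volume V bounded by a smooth convex surface
Σ, illuminated by Lambertian radiance I0 in an external medium of index
ne, the RTE has invariant solutions in each sub-volume of index nj:
radiance I_j = (nj/ne)² I0 in every direction and position, fluence rate
Φ_j = 4π(nj/ne)² I0, and mean partial path length ⟨L_j⟩ = 4(nj/ne)² V_j/Σ.
These are independent of the scattering coefficient and phase function —
which makes them ideal for testing boundary handling in isolation.  For a
slab illuminated on both faces, V_j/Σ = s_j/2, hence ⟨L_j⟩ = 2 s_j(nj/ne)².

The exception is a *non-scattering* slab with nj > ne: directions with
n sin θ above the largest Snell invariant that can enter from outside are
unreachable ("trapped"), the radiance support shrinks to
|cos θ| ≥ cos θ_max with sin θ_max = min(ne, indices crossed)/nj along the
less restrictive entry side, and fluence and path length acquire the
factor (1 − cos θ_max).  The support rule is validated against a
brute-force Snell-chain ray-tracing oracle in the tests.

The simulator realizes Lambertian illumination by reciprocity: photon i is
injected at a single point of face (i mod 2) — alternating sides — with a
cosine-weighted external direction, Fresnel-refracted at entry.  Photons
specularly reflected at entry contribute zero internal path but count in
N: the invariant solutions hold under illumination of the physical
boundary, including what it reflects.  Inside, free flights carry a
residual optical depth τ ~ Exp(1) across interfaces (memorylessness makes
this equivalent to resampling, with fewer draws); non-scattering layers
propagate straight to the next interface.  Every crossing applies
unpolarized Fresnel reflectance — exactly 1 in the TIR regime — and Snell
refraction that conserves n sin θ to machine precision.  The kernel tracks
the current layer index explicitly, so an interface can never be
re-detected and no positional epsilon is needed.  A cap of 10^7 events per
photon guards against pathological configurations; aborted photons are
counted and any nonzero count fails verification rather than biasing it
silently.

Estimators, under the unit-incident-flux normalization (I0 = 1/π):

- ⟨L_j⟩: mean over photons of the path accumulated in layer j, SE from
  the per-photon variance;
- Φ_j = 2⟨L_j⟩/s_j (power per unit area entering the slab is 2);
- radiance I_j(θ_b) = (2/s_j) · (track length in bin)/(N ΔΩ_b) on a
  uniform-in-θ grid with exact per-bin solid angles ΔΩ_b (default 180
  bins).  Summing the radiance bins times ΔΩ_b reproduces Φ_j to rounding
  error, which the suite asserts.

Radiance standard errors use the spread of 50 batch means: per-photon
per-(layer, bin) bookkeeping would cost O(layers × bins) memory per
photon for no accuracy gain at these N.  Path-length SEs stay per-photon.

## Verification harness

Step 1 tests every tallied moment with an available closed form; the
transverse tallies of the first scattering order are identically zero for
a pencil beam and are compared for exact equality instead of t-tested.
Step 2 tests per-layer fluence and path lengths, the total path length,
and optionally every radiance bin (with the bin-averaged benchmark,
including partial support bins in the trapped regime).  p-values use the
normal tail above n = 10^4, Student's t below.  No multiple-testing
correction is applied; each report states the expected number of false
rejections α·(tests) and passes while the rejection count stays within a
3σ binomial allowance of it.

Because records within one run share photons (l_1 ≡ z_1 exactly;
d² = ρ² + z²; all orders of one trajectory), the distribution-of-t
calibration check draws *one* record per independent seed, cycling
through the battery labels — a pooled KS test over correlated records
would reject a correct code by construction.

Sensitivity is demonstrated with three injected defects, shipped as
explicit switches on the slab kernel: (a) an HG sampler biased to
g′ = 0.905 tested against g = 0.9 benchmarks — the ⟨z₂⟩ shift of 0.005 mm
is ≈11 SE at N = 10^7, comfortably above the |t| > 5 detection threshold,
so the fixture runs at 10^7 rather than 10^8 photons; (b) Fresnel
reflectance computed with the two indices swapped (a literal s/p-formula
swap leaves the unpolarized mean (r_s² + r_p²)/2 unchanged and is
undetectable in principle, so the classic wrong-critical-angle bug is
injected instead); (c) a missing TIR branch that passes trapped photons
through unchanged.  Defect (c) is detected on the decreasing-index
non-scattering slab: with an increasing profile and ne = 1 the Snell
invariant never exceeds any layer index and TIR never fires, so only the
decreasing profile (ne = 2) exercises that branch.

## Study configurations

The published verification conditions are: μs = 1 mm⁻¹; phase functions
HG g = 0 (g2 = 1/3), HG g = 0.9 (g2 = 2.62/3) and Rayleigh (g2 = 2/5);
a four-layer slab of 2.5 mm layers and a hundred-layer slab of 0.1 mm
layers, each with an increasing ("up", ne = 1) and a decreasing ("dw",
ne = 2) refractive-index profile.  The numeric index values appear only
in figures, so the package fixes them once: 1.2/1.4/1.6/1.8 for the
four-layer profiles and a linear ramp 1.01…2.00 for the hundred-layer
profiles (reversed for "dw") — monotone between 1 and 2 with the stated
external indices.

Problem sizes in the test suite are chosen for a single CPU: N = 10^6 for
the headline step-1 and four-layer checks, 10^8 for the 1/√N scaling
check (first order only), 10^7 per phase function for the order-1..10
distance recursion, and 10^6 for the hundred-layer trapped-regime run
(the published hundred-layer figures use cluster-scale N = 10^8–10^10;
all statistical assertions here scale their SE accordingly, so the checks
are equally sharp at the reduced N).

## What the tests do and do not show

The synthetic configurations exercise exponential free paths, the three
phase-function samplers, Fresnel/Snell boundary handling with TIR, and
the track-length estimators — against *exact* references, so a pass
constrains the transport core tightly.  They do not exercise absorption
weighting, time resolution, finite lateral extent, curved boundaries, or
Mie-type tabulated phase functions; agreement here says nothing about
those features.  And as with all verification by testing, a pass bounds
the size of surviving errors (relative to the SE at the tested N) rather
than proving their absence — only a failure is conclusive.

## Numerical choices

- Accumulation in double precision; numpy pairwise block sums for the
  vectorised tallies.
- u = 0 uniforms remapped to 2^−53 before −ln(u).
- Direction renormalized after every rotation; near-axial guard at
  |μz| > 1 − 1e−12.
- Grazing entry cosines clamped at 10^−12; a photon with |μz| < 10^−12 in
  a void layer cannot progress and is counted as aborted (probability
  zero under the samplers).
- Radiance bin index from arccos(μz) on a uniform θ grid; normalization
  uses exact solid angles so flatness tests are unbiased.
- CSV exports format floats with %.12g, making identical (seed, config)
  runs byte-identical.
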