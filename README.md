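# photonbench

Monte Carlo photon transport in non-absorbing infinite media and layered
slabs, bundled with the exact radiative-transfer solutions needed to verify
the simulator statistically.

Monte Carlo codes are the workhorse of tissue optics, and a subtle bug in a
sampler or a boundary routine produces numbers that merely *look* plausible.
`photonbench` implements a two-step verification method built on two
families of exact RTE results:

1. **Trajectory extraction** — in an infinite medium with scattering
   coefficient μs and a phase function with moments g = ⟨cos θ⟩,
   g2 = ⟨cos² θ⟩, the coordinates of the k-th scattering event of a pencil
   beam have closed-form moments, e.g. ⟨z₁⟩ = 1/μs, ⟨z₂⟩ = (1+g)/μs,
   ⟨d_k²⟩ = 2(k − (k+1)g + g^{k+1})/(μs(1−g))², ⟨l_k^m⟩ = k(k+1)⋯(k+m−1)/μs^m.
   These are exquisitely sensitive to the phase-function sampler.
2. **Boundary handling** — a non-absorbing body under Lambertian
   illumination I₀ has invariant solutions in every sub-region of index nj:
   radiance (nj/ne)² I₀ in all directions, fluence 4π(nj/ne)² I₀, and mean
   partial path length 4(nj/ne)² Vj/Σ (= 2 sj (nj/ne)² per slab layer).
   These are *independent of the scattering properties* and hence isolate
   Fresnel/Snell and intersection code.  For a non-scattering slab with
   nj > ne, trapped trajectories reduce the angular support to
   |cos θ| ≥ cos θ_max and scale fluence and path lengths by (1 − cos θ_max).

Every Monte Carlo estimate carries a standard error, so each comparison is
a one-sample t-test on the normalized deviation
t = (MC − exact)/SE; a correct code keeps ≈95% of deviations within two
standard errors and rejects at the nominal α rate.  The package also ships
three *injected defects* (a biased HG sampler, swapped Fresnel indices, a
missing total-internal-reflection branch) to demonstrate that the battery
actually detects broken physics.

## Worked example

Step 1 — one million trajectories in an infinite medium, Henyey–Greenstein
g = 0.9, μs = 1 mm⁻¹, orders 1–4:

```sh
$ photonbench step1 --phase hg --g 0.9 --mus 1 -N 1e6 --kmax 4 --seed 1 \
      --out step1.json --csv step1.csv
verification step 1: 40 comparisons, 3 rejected at alpha=0.05 (expected ~1.8 false rejections)
max |t| = 2.80; aborted photons: 0
PASS
```

Forty moments are tested (the structurally zero first-order transverse
tallies are checked for exact equality instead).  Three rejections against
an expectation of two, and a largest deviation of 2.8 standard errors, is
exactly the behaviour of a correct code at α = 0.05.  Inside the report,
e.g. the second-order mean depth ⟨z₂⟩ (exact value 1 + g = 1.9 mm):

```json
{"label": "hg(g=0.9):k=2:z", "estimate": 1.8995232, "se": 0.0013928,
 "benchmark": 1.9, "t": -0.342, "p": 0.732, "reject": false}
```

and the CSV carries the estimates with their relative errors — the
first-order depth shows the textbook 1/√N = 10⁻³ relative error at N = 10⁶:

```
k,quantity,mean,se,rel_se,n
1,z,0.999331300832,0.000998605346266,0.000999273559664,1000000
```

Step 2 — a four-layer slab (2.5 mm layers, n = 1.2/1.4/1.6/1.8, ne = 1,
μs = 1 mm⁻¹) under Lambertian illumination, realized by alternating-side
cosine-weighted point injection:

```sh
$ photonbench step2 --slab four_layer_up -N 1e6 --seed 1 --bins 180 \
      --out step2.json --prefix up
verification step 2: 9 comparisons, 0 rejected at alpha=0.05 (expected ~0.5 false rejections)
max |t| = 1.20; aborted photons: 0
PASS
```

The per-layer fluence estimates land on the invariant values
Φj = 4 (nj/ne)² — 5.76, 7.84, 10.24, 12.96 W m⁻² for these indices —
within one to two standard errors:

```
layer,estimate,se
1,5.76263678311,0.00853405177145
2,7.85806229278,0.0150960650484
3,10.2480305168,0.0189097873817
4,12.9816819697,0.0206794737353
```

Slab geometries are TOML files (see `src/photonbench/configs/`); the four
shipped fixtures (`four_layer_up`, `four_layer_dw`, `hundred_layer_up`,
`hundred_layer_dw`) cover the four-layer and hundred-layer increasing and
decreasing index profiles, and `--mus 0` switches any of them to the
non-scattering trapped regime.  Everything is equally accessible as a
library:

```python
import photonbench as pb

report = pb.verify_step2(pb.four_layer_slab("up"), n_photons=10**6, seed=1)
print(report.summary_text())

exact = pb.infinite_moments(k=3, g=0.9, g2=2.62/3, mus=1.0)
print(exact.z, exact.x2)   # 2.71  0.46993...
```

## Layout

- `photonbench.sampling` — free paths, HG/Rayleigh cosines, direction
  rotation, Lambertian launch directions
- `photonbench.infinite_sim` — step-1 simulator and moment tallies
- `photonbench.benchmarks` — all closed-form reference values
- `photonbench.slab_sim` — step-2 layered-slab simulator (numba kernel),
  track-length estimators for radiance/fluence/path lengths
- `photonbench.verify` — t-test records, reports, defect fixtures
- `photonbench.cli_io` — CLI, TOML/JSON/CSV readers and writers

`docs/methods.md` documents the model, the estimators, the numerical
choices and the limitations in detail.
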