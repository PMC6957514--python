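# memkin

Quantitative analysis of how annexin-V (A5) 2D-lattices order the membrane
beneath them — for biophysicists working with HS-AFM movies of supported
lipid bilayers, confocal FRAP/Laurdan imaging of GUVs, and lipid
trajectory data.

A5 is a Ca²⁺-dependent phospholipid-binding protein that self-assembles
into honeycomb trimer lattices (unit cell a = b = 17.7 nm, γ = 60°) on
phosphatidylserine-rich membranes. `memkin` implements the measurement
chain used to show that these lattices stabilize and order the underlying
bilayer:

* **Border kinetics** — segment three-level AFM height movies
  (mica 0 / membrane 3.15 / lattice 6.1 nm), project the lattice border to
  polar coordinates r(θ, t), idealize kymographs into ±8.85 nm trimer
  steps, and fit dwell times: k̂_a = n_assoc/T_obs, k̂_d = n_dissoc/T_obs
  (competing-risks MLE; dwells are Exp(k_a + k_d)), K_eq = k_a/k_d.
  Radius-change occurrence histograms N(Δr) invert into an energy diagram
  ΔG(Δr) = −k_BT ln N.
* **Topography** — three-Gaussian height-histogram fits (membrane and
  A5-covered thickness), patch area/coverage, aggregate counting with a
  200 nm² floor, mass-center tracking, perimeter/area fusion metrics, drift
  correction.
* **FRAP** — double-normalized recovery curves, model-free half time τ½,
  effective bleach radius r_e from the first post-bleach frame, and
  D = (r_n² + r_e²)/(8 τ½).
* **Laurdan GP** — GP = (I₁ − G·I₂)/(I₁ + G·I₂) imaging with G-factor
  calibration (⟨GP⟩ = 0 in the A5-free reference), histograms/peaks/means
  over GUV ring masks, sum-based time-lapse GP, and GUV diameter by the
  360-fold radial average.
* **Geometry** — unit-cell area (271.3 nm²), trimer step (8.85 nm), and the
  local Ca²⁺ concentration above the bilayer implied by 2–11 ions per
  monomer in a 1 nm slab (110–606 mM).
* **Trajectories** — overlapping-origin MSD and D = MSD(τ)/(2dτ), acyl-chain
  order S_CD = ⟨P₂(cos α)⟩, and box-area shrinkage windows.

Every modality has a synthetic-data generator with exactly known ground
truth (`memkin.synthetic`), so each pipeline is validated by parameter
recovery; see `docs/methods.md` for models, defaults, and limitations.

## Worked example

Simulate a lattice-border movie at the experimentally measured rates and
recover them end-to-end (segmentation → polar border → kymograph
idealization → dwell times → rates → energy diagram):

```python
import numpy as np
import memkin as mk

params = mk.LatticeSimParams(
    n_frames=200, frame_interval=0.05, n_theta=64,
    k_assoc=2.3, k_dissoc=2.0, seed=1,
)
movie, truth = mk.generate_afm_lattice_movie(params)
result = mk.analyze_movie(movie, n_theta=64)

rates, energy = result["rates"], result["energy"]
print(f"simulated events : {len(truth['events_t'])}")
print(f"k_assoc          : {rates.k_assoc:.2f} 1/s  (true 2.30)")
print(f"k_dissoc         : {rates.k_dissoc:.2f} 1/s  (true 2.00)")
print(f"K_eq             : {rates.K_eq:.3f}      (true 1.150)")
finite = np.isfinite(energy.delta_G)
amin = energy.delta_r_steps[finite][np.argmin(energy.delta_G[finite])]
print(f"energy minimum at: dr = {amin} steps of 8.85 nm")
```

prints

```
simulated events : 2720
k_assoc          : 2.20 1/s  (true 2.30)
k_dissoc         : 1.92 1/s  (true 2.00)
K_eq             : 1.148      (true 1.150)
energy minimum at: dr = 0 steps of 8.85 nm
```

The recovered rates sit a few percent below truth — the residual bias of
frame-sampled kinetics (an association and a dissociation inside one frame
cancel); K_eq is unaffected because both channels are biased alike. The
energy diagram's minimum at Δr = 0 says the border is at equilibrium: no
net change between consecutive frames is the most probable observation.

The same stages are available from the shell:

```sh
$ memkin geometry
area = 271.3 nm^2, step = 8.85 nm, local Ca2+ = 110-606 mM

$ memkin generate afm-lattice --seed 1 --n-frames 200 --frame-interval 0.05 --out run
$ memkin afm-kinetics --movie run/movie.tif --n-theta 64 --out run/kinetics
```

plus `memkin {generate frap|generate guv|generate brownian|afm-topo|frap|gp|traj}`
and `memkin run --config run.yaml` for config-driven, manifest-logged runs.

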