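# Methods

`memkin` quantifies how annexin-V (A5) 2D-lattices order the lipid membrane
beneath them, across the observables used in that line of experiments:
HS-AFM lattice-border kinetics, AFM height/area topography, FRAP lipid
diffusivity, Laurdan generalized polarization (GP), lattice geometry /
local-Ca²⁺ arithmetic, and trajectory observables (MSD diffusivity, S_CD
order parameters). Because raw experimental movies of this kind are rarely
deposited, every analysis ships with a synthetic-data generator whose ground
truth is known exactly; the tests and the acceptance script measure how well
each pipeline recovers that truth under realistic conditions.

## Border kinetics (`border_kinetics`, generator in `synthetic`)

**Model.** A finite A5 lattice on a membrane patch has a dynamic border.
Per angular bin about a fixed center, the border radius r(θ, t) is modeled
as a birth–death jump process: exponential waiting times with association
rate k_a and dissociation rate k_d per bin, jumps of ±8.85 nm (half the
17.7 nm unit cell — one trimer row), reflected at 0 and at the patch
radius by suppressing the outward/inward rate at the boundary. Bins are
simulated independently; real borders are spatially coupled, but
independence gives closed-form expectations (event count (k_a+k_d)·T per
bin, dwell times Exp(k_a+k_d)) against which every stage is tested.

**Analysis chain.** Frames are segmented by nearest height level (mica 0,
membrane 3.15, lattice 6.1 nm; largest connected lattice component kept),
the border is projected to polar coordinates about the frame-0 lattice mass
center (120 bins of 3° by default; radius = outermost lattice pixel per
bin), kymographs r(t) are idealized by a change-point step fit (new segment
when the running median departs from the current level by more than half a
step; levels snapped to the step grid), and dwell times are pooled with
first/last segments censored.

**Rate estimation.** Association and dissociation compete at the border, so
*every* dwell is Exp(k_a + k_d) and the sign of the following step selects
the channel. The per-channel rates therefore come from the competing-risks
MLE k̂_a = n_assoc/T_obs, k̂_d = n_dissoc/T_obs (equivalently: total rate
from the pooled dwells, split by event fractions); fitting 1/mean to each
dwell list separately would return the *total* rate twice. A classical
histogram-exponential fit of the pooled dwells is available as an
alternative total-rate estimator.

Dwells measured from a movie are whole-frame quantized (geometric, success
probability p per frame), so the default pipeline applies
k_tot = −ln(1 − 1/m̄)/Δt with m̄ the mean dwell in frames. The remaining
bias is event cancellation within one frame (an up and a down step between
two samplings), of order (k_aΔt)(k_dΔt) per frame; at the recommended
sampling k_totΔt ≈ 0.2 this leaves a ≈5% underestimate. At
k_totΔt ≳ 1 — e.g. rates of a few per second sampled at 0.3 s/frame —
frame-sampled dwell analysis cannot resolve individual events (the
generator warns in this regime); quantitative rate-recovery studies here
use Δt = 0.05 s with the study rates k_a = 2.3 s⁻¹, k_d = 2.0 s⁻¹, which
recovers both rates within ~7% and K_eq = k_a/k_d within ~1%.

**Energy diagram.** The occurrence histogram N(Δr) of radius changes
between frames t and t+lag (pooled over all bins; total count exactly
n_bins·(n_frames−lag)) is Boltzmann-inverted as ΔG = −k_BT ln N. The zero
of energy sits at N = 1, so never-visited positions define the zero level
and the minimum falls at the most frequent Δr (Δr = 0 for any near-
equilibrium border). For symmetric rates the profile is symmetric within
counting noise (ΔG(+1)−ΔG(−1) = ln(N₋/N₊), sd ≈ √(1/N₊+1/N₋)).

## Topography (`topography`)

Pixel-height histograms are fit with a three-Gaussian mixture (peak-picked
initialization on a Savitzky–Golay-smoothed, zero-clipped histogram; widths
bounded below by half a bin so noise-free, discrete histograms do not
collapse the fit). Membrane thickness = center₂−center₁ and A5-covered
thickness = center₃−center₁ are offset-invariant; `rezero_to_mica` pins the
mica mode at 0. Patch metrics use 8-connected components, area =
pixel count × pixel_size², perimeter = boundary-pixel count × pixel_size
(boundary counting overestimates a disk's circumference by a known O(1)
factor; the fusion metric perimeter/area is used comparatively, where the
factor cancels), aggregate counting applies a 200 nm² minimum-size floor,
and drift correction is integer-pixel phase correlation against frame 0.
The five qualitative self-assembly periods sometimes drawn on such series
are annotations a user supplies; no automatic classifier is attempted.

## FRAP (`frap`)

The generator bleaches instantaneously with a Gaussian dip
I(ρ,0) = 1 − K·exp(−2ρ²/r_e²) (1/e² radius r_e, the *effective* bleach
radius) centered in a nominal ROI of radius r_n, and evolves the mobile
part by exact free 2-D diffusion (variance 2Dt per axis); an immobile
fraction keeps the frozen profile, and the A5 channel is fully immobile.

The analysis follows the simplified circular-bleach relation
D = (r_n² + r_e²)/(8·τ½), with r_e fit from the azimuthally averaged radial
profile of the **first** post-bleach frame only (diffusion broadens later
frames; strongly non-Gaussian profiles are flagged by a residual test) and
τ½ from the double-normalized ROI curve
I_norm = [(I_bleach−I_bg)/(I_ctrl−I_bg)] / pre-bleach mean, which is exactly
invariant to per-frame global intensity scaling (photofading).

Two numerical facts drove the defaults:

* τ½ is the **model-free half-recovery crossing**, with the plateau I_∞
  taken from whichever of two tail models fits better — a single
  exponential or the hyperbola I_∞ − b/(t+c), the exact late-time form of
  2-D diffusive recovery. A single-exponential τ·ln 2 is 30–90% slow on
  diffusive recoveries (their tail is hyperbolic, not exponential) and is
  provided only as an explicit option.
* The simplified relation is exact as r_n/r_e → 0 and accurate to a few
  percent for r_e ≳ 2 r_n, but ~21% biased at r_e = r_n (evaluated on the
  closed-form disk average of the evolving Gaussian). Generator defaults
  are r_n = 1 µm, r_e = 2 µm — a realistic confocal geometry and a regime
  where the published formula is valid on its own terms. End-to-end
  recovery at D ∈ {2.6, 0.4, 1.7} µm²/s (the bare / A5-covered /
  EDTA-recovered study values) is within ~5%.

## Laurdan GP (`gp`)

GP = (I₁ − G·I₂)/(I₁ + G·I₂) per pixel, with the gain G calibrated so the
reference (A5-free) condition has ⟨GP⟩ = 0: G = ΣI₁/ΣI₂ over the mask
(exact for sum-based GP; a root-found pixel-mean variant is also provided).
Two estimators are kept distinct and never interchanged: the per-pixel GP
image (histograms with 0.01 bins, most-probable peak, masked mean) and the
sum-based time-lapse GP from whole-mask channel sums, alongside
background-corrected, peak-normalized A5 intensity. GUV diameter uses the
360-fold average: intensity-centroid center (refined over a small pixel
grid by maximizing the profile peak), mean radial profile over 360 angular
sectors, diameter = twice the profile-peak radius. The ring mask is
±2 radial bins about the profile peak; pixels below 2% of the masked median
total intensity have undefined GP. The generator splits a Gaussian-
cross-section ring as I₁ = T(1+gp)/2, I₂ = T(1−gp)/(2G) so the GP equation
returns gp exactly at every pixel before noise.

## Geometry (`geometry`)

Pure arithmetic on the lattice unit cell (a = b = 17.7 nm, γ = 60°,
area a·b·sin γ = 271.3 nm², trimer step a/2 = 8.85 nm) and the local Ca²⁺
concentration c = n_ions/(N_A·V) for ions carried by the 9 monomers of one
cell confined to a 1 nm slab: 2–11 ions/monomer maps to 110–606 mM. The
per-structure ion-count table behind the 2–11 range is user input; only
min/max/mean bookkeeping is provided.

## Trajectories (`trajectories`)

MSD uses all overlapping time origins (sample counts reported so
non-overlapping averages can be recomputed); D = MSD(τ)/(2dτ) at a stated
lag, or a through-origin linear fit, with a log–log slope diagnostic
flagging anomalous diffusion instead of modeling it. S_CD = ⟨P₂(cos α)⟩ per
carbon against the bilayer normal, reported as raw ⟨P₂⟩ in [−0.5, 1] with
no sign convention applied; chains (sn-1/sn-2) can be pooled by
count-weighted averaging. Box shrinkage reports the percent area change per
stated window plus the compounded cumulative change. The bond-vector
generator samples the axial density p(cos α) ∝ exp(κ cos²α) by inverse CDF;
its ground-truth S comes from numerical quadrature (0 at κ=0, →1 as κ→∞).

## Noise defaults and what the generators do not emulate

AFM height noise is Gaussian, sd 0.1 nm (instrument-grade vertical noise;
no tip-convolution or scan-line artifacts); fluorescence noise is Gaussian
read noise at 1% of full scale (Poisson available for the GUV rings); the
bleach is instantaneous and optics are ideal beyond the Gaussian
bleach/ring cross-sections. Border bins are kinetically independent.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated stochastic models — not robustness to tip artifacts,
drift-coupled noise, spatially correlated border fluctuations, or detector
nonlinearity.

## Problem sizes

Recovery studies use: 200-frame, 256² px border movies at 64 angular bins
(~2,700 events); 310-frame, 200² px FRAP fields; single-frame 253² px GUV
rings; 320 particles × 2500 steps for MSD; 10⁶ bond vectors. All generators
are deterministic under a fixed seed, and every ground-truth log records
the seed and parameters.

## Known limitations

* Rates are biased low by within-frame event cancellation; keep
  (k_a+k_d)·Δt ≲ 0.2 or treat recovered rates as lower bounds.
* The simplified FRAP relation inherits its r_e ≳ 2 r_n validity window;
  for r_e ≈ r_n a full reaction–diffusion fit (out of scope here) is
  needed.
* Perimeter by boundary-pixel count is resolution-dependent; compare fusion
  ratios only within a movie at fixed pixel size.
* The GP mask and histogram binning affect the most-probable peak at the
  0.01 level; means over the ring mask are the stabler summary.
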