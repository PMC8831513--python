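# Methods

## Model overview

The package simulates 665-nm light delivery into a drained abscess cavity
and converts the resulting wall fluence into a treatment plan.  The domain
is a voxel grid partitioned into three homogeneous regions:

| region | μa (cm⁻¹) | μs (cm⁻¹) | g | n |
|---|---|---|---|---|
| exterior tissue (label 0) | 0.2 | 100 | 0.9 | 1.4 |
| abscess wall (label 1) | 0.2–10 (swept) | 100 | 0.9 | 1.4 |
| cavity interior (label 2) | 0–0.17 (swept) | 0–100 (swept) | 0.7 | 1.33 |

The two clinically tunable agents map linearly onto the swept coefficients:
methylene blue contributes 0.17 cm⁻¹ of absorption per μM (so the top of
the wall range, 10 cm⁻¹, corresponds to ≈ 59 μM), and Intralipid contributes
100/2.3 ≈ 43.5 cm⁻¹ of scattering per percent (v/v lipid).  Wall absorption
is modeled as the total μa with no additive tissue baseline; the 10 cm⁻¹ ↔
~60 μM pairing implies none, and a configurable baseline would enter as a
simple offset.  An independent Mie-based power law for Intralipid
(μs = 16 λμm⁻²·⁴ cm⁻¹ per percent, with g(λ) = 1.1 − 0.58 λμm ≈ 0.71 at
665 nm) is included purely as a cross-check; inverting it at 100 cm⁻¹
recovers 2.3%, and its anisotropy matches the fixed cavity g of 0.7.  The
linear anchor — not the power law — drives all sweeps so that concentration
axes are exactly reproducible.

## Monte Carlo transport

Weighted photon packets (MCML lineage) propagate on the voxel grid:

* **Source.**  A flat-cleaved fiber (400 μm core, NA 0.22, n = 1.46) at the
  cavity centroid: launch positions uniform over the core disk, directions
  uniform in solid angle within the acceptance cone computed in the launch
  medium, half-angle asin(NA/1.33) = 9.52°.  Fresnel loss at the fiber face
  is folded into the delivered ("out-of-fiber") power, which is the quantity
  the clinical laser reports.  An isotropic point source is available for
  validation runs.
* **Free flight.**  A dimensionless scattering depth τ = −ln ξ is sampled
  once and consumed per voxel (τ ← τ − μs ℓ) across boundaries, which keeps
  heterogeneous traversal unbiased.  In regions with μs = 0 the packet
  free-flies to the next face; no interaction is sampled.
* **Absorption and tally.**  Absorption is applied continuously along each
  segment, w ← w·exp(−μa ℓ), and the track-length estimator tallies
  ∫w ds = w(1 − e^(−μa ℓ))/μa per voxel (w ℓ when μa = 0).  This estimator
  is well-defined in the non-absorbing cavity, which is why it was chosen
  over absorption-weight deposition.
* **Scattering.**  Henyey–Greenstein via the closed-form inverse CDF;
  isotropic when g = 0.
* **Boundaries.**  Unpolarized Fresnel reflectance (R = 1 beyond the
  critical angle) and Snell refraction at any voxel face where the region
  refractive index changes; the outer grid boundary is absorbing and tallies
  escaped weight.  The phantom generator pads ≥ 1 cm of exterior tissue
  around the wall so domain truncation is negligible (μeff ≈ 2.5 cm⁻¹ in
  the exterior, i.e. the pad is ~2.5 attenuation lengths).
* **Termination.**  Russian roulette below weight 10⁻⁴ with survival
  probability 0.1.  Both the killed weight and the survival boost are folded
  into the absorbed tally, so `absorbed + escaped = launched` holds to
  floating-point precision on every run — the suite asserts 10⁻⁶.
* **Randomness.**  Each packet draws from its own SplitMix64 stream keyed
  by (seed, packet index), so results are bit-reproducible and independent
  of execution order; per-task seeds in sweeps are derived by stable hashing
  of (master seed, task key), so enlarging a grid never perturbs existing
  cells.

Fluence maps are stored per unit delivered power ((mW/cm²)/mW ≡ cm⁻²) and
scaled linearly to any power, which makes threshold-power computation a
closed form rather than a search.

Validation oracles (all in the test suite): 1/(4πr²) in a transparent
medium and e^(−μa r)/(4πr²) in a purely absorbing one (within 5%);
diffusion theory φ = 3μtr P e^(−μeff r)/(4πr) in a bulk scattering medium
(within 15% over 0.5–1.5 cm; measured agreement is ~1% with the boundary
≥ 0.9 cm away); doubling N preserves means and halves variance.

## Geometry

Phantoms voxelize analytic shapes (cavity = voxel centers inside the shape)
on CT-like, possibly anisotropic grids; the lobulated generator unions
seeded, jittered ellipsoids and keeps the largest 6-connected component,
producing the concave morphologies seen in irregular pelvic abscesses.  The
wall is the shell of configurable thickness (default 0.2 cm — the scale of
the enhancing rim on contrast CT, and more than one transport mean free
path at μs = 100 cm⁻¹, so deeper tissue is optically shadowed) extracted by
thresholding the Euclidean distance transform; the threshold carries a
min(spacing)/3 sub-voxel offset because the EDT measures to cavity voxel
centers, which lie ~h/3 inside the continuum surface — with it, shell
volumes match the analytic value to ~5% at 1 mm voxels, converging with
refinement.  Invariants (single 6-connected cavity, wall separating cavity
from exterior) are validated exhaustively.

The dose-sampling surface is the innermost wall layer (wall voxels
6-adjacent to cavity).  Each voxel's representative area is its
cavity-facing face area projected onto the local surface normal (gradient
of the lightly smoothed signed distance field), which removes the ~1.5×
staircase overcount; sphere surface areas come out within ~3%.

The fiber tip sits at the unweighted centroid of cavity voxel centers.  For
strongly concave shapes the centroid can fall outside the cavity; it is
still reported, flagged, and rejected by the simulator as a source position
(mirroring the clinical reality that the catheter is advanced only to the
approximate center).

## Planning

All wall statistics are area-weighted with lower inverted-CDF quantiles.
The coverage goal is read as "the under-dosed wall-area fraction is
strictly below 5%", which makes `P_th = T/q05` *exactly* the minimum
feasible power (a brute-force 0.1-mW power scan with direct area counting
pins this convention in the tests); the hotspot rule counts voxels
"receiving ≥ 400 mW/cm²" (closed inequality), evaluated at `P_th`, and the
power ceiling is strict ("less than 2000 mW").  Equivalently, eligibility
is `T/q05 < 2000` and `q95/q05 < H/T = 100`.  Comparisons carry ~10⁻⁹
relative guards so exact-boundary cases (e.g. 5 of 100 equal-area voxels)
are decided by the convention, not by float rounding.

The optimal Intralipid concentration is the simulated concentration
minimizing `P_th` at fixed wall absorption — argmin over grid values only,
no interpolation, ties to the lower concentration; if every concentration
is ineligible the best cell is still reported with `eligible=False` so
sweep tables stay rectangular.  The uniform-dose comparator fixes the
concentration at the grid value nearest 1% (within 0.5 percentage points)
and optimizes power only; by argmin dominance it can never beat the
optimized plan, and the suite asserts this on every cell.

Case-2 sweeps (intracavity absorption from leaked methylene blue) evaluate
three knowledge levels per cell: `fixed-plan` (power and concentration
frozen at the μa,cavity = 0 plan), `power-only` (concentration frozen,
power re-optimized), and `full` (both re-optimized).  Because the modes are
nested optimizations over shared fluence maps, eligibility obeys
full ≥ power-only ≥ fixed-plan deterministically.

Sweep tables are summarized with a tie-corrected Friedman test (implemented
directly so the two-treatment case works; asymptotic χ² p-values, verified
against scipy and against exhaustive permutation enumeration in the tests)
and the Wilcoxon signed-rank test (scipy, exact or normal approximation as
selected per call) for paired eligibility comparisons.

## What the synthetic phantoms do and do not show

The generator reproduces the *morphological regime* of the study population
— closed single cavities up to 8 cm, spherical through lobulated, on
anisotropic CT-like grids — so trend-level conclusions (threshold power
rising with wall and cavity absorption, optimized planning dominating the
uniform dose, the integrating-sphere buildup) transfer.  It does not
reproduce any particular patient anatomy: real cavities have rougher walls,
partial-volume segmentation noise, and non-uniform wall optics, so absolute
eligibility percentages computed on phantoms are illustrative, not
cohort estimates.

## Problem sizes and numerical choices

Default runs use 10⁵ packets; planning quantiles on a ~3–4 cm cavity are
then stable to a few percent, and a single cell simulates in seconds to
tens of seconds on one CPU core.  Transport oracles run on 64³ homogeneous
grids (0.05 cm spacing, 0.075 cm for the diffusion check so the 1.5-cm
radius stays ≥ 0.9 cm from the absorbing boundary).  The monotonicity
checks use a 4-cm-diameter-class spherical cavity (radius 2 cm, 0.1 cm
voxels, 0.2 cm wall, 1 cm pad) with a clear interior (0% Intralipid, a grid
value of the study conditions) across three seeds.  Degenerate inputs are
rejected early: phantoms below one voxel, walls thinner than a voxel,
cavities over the 8-cm exclusion limit, empty masks, sources outside the
cavity, |g| ≥ 1, negative concentrations or powers.

## Known limitations

Uniform optics within each region; single fiber, fixed at the centroid with
a fixed axis; no photobleaching, no time resolution, no polarization, no
thermal model beyond the fluence-rate hotspot proxy; CPU engine at reduced
packet counts rather than a GPU implementation; NIfTI-1 masks only (no
DICOM series handling).
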