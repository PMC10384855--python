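# Methods

## Nuclear data

Half-lives and summarized emission tables live in one versioned constants
file (`theradose/data/nuclides.json`): ⁸⁹Zr t½ = 78.41 h, ¹⁷⁷Lu
t½ = 6.647 d = 159.53 h.  ¹⁷⁷Lu is represented by a single charged line at
147.9 keV carrying the total mean charged-particle energy per decay (β mean
plus conversion/Auger electrons) with yield 1, and its two principal photon
lines, 208.4 keV at 0.104/decay and 112.9 keV at 0.062/decay; ⁸⁹Zr by its
mean β⁺ line, annihilation photons and the 909 keV gamma.  Absolute dose
values inherit whatever emission table is configured; users can load their
own constants file of the same schema.  Gamma dose-rate constants are
screening values for the point-source external dose estimate (Γ·A/d², no
self-attenuation — an upper bound for release decisions, not reproduced
against any measurement).

Decay arithmetic uses injection time as t = 0 everywhere.  Isotope
substitution multiplies each voxel by `exp((λ_img − λ_th)·t)`; because
λ(⁸⁹Zr) > λ(¹⁷⁷Lu) the factor is ≥ 1 and increasing in t, and substituting
back recovers the input to floating tolerance.

## Synthetic phantom

The generator emulates the statistical structure the analysis assumes, not
anatomy.  Geometry: a 64×64×128 grid at 4 mm isotropic (a desk-scale stand-in
for a 256×256 / 2.5 mm acquisition); a body ellipsoid (~9.6 L, soft tissue
1.04 g/cm³, giving ~10 kg) containing ellipsoid/cylinder organs — heart,
liver, spleen, adrenals, kidneys, spinal and shoulder marrow (1.03 g/cm³,
each wrapped in a 1.4 g/cm³ cortical-bone shell that exercises the density
division in the dose engines), and testes for male subjects only.  Subject
mass defaults to the integral of the density map.

Kinetics: the injected activity is partitioned at t = 0 into per-organ
pathways plus a remainder-of-body pool (blood and unassigned tissue, so SUV
denominators stay honest).  Each pathway is a catenary pair — precursor
`f·e^{−k_up t}` feeding the organ, organ clearing at `k_bio` into urinary /
hepatobiliary excreta per a fixed route split — giving the closed form
`b(t) = f·k_up/(k_up−k_bio)·(e^{−k_bio t} − e^{−k_up t})` for organ-resident
biological content.  Organ content is spread uniformly over the organ's
voxels; precursor activity resides in the remainder region.  Mass balance
(resident + excreted = injected, decay-corrected) closes to 1e-9 by
construction, and every frame's activity is bounded by the decayed injected
activity.

Default rates were chosen once to reproduce the documented qualitative
behavior and are not fitted to any plotted curve: liver is the dominant sink
(f = 0.30), adrenals are small but avid (highest SUV after liver), marrow
uptake is slow and persistent (SUV rising through 73 h), the heart behaves
as a fast-clearing blood pool (SUV falling ~3.2 → 0.1), testes retention is
very low, and the remainder pool clears at 0.03 h⁻¹ so that ~76% of the
one-week biological excretion has occurred by 73 h (the 73 h/168 h ratio of
total excreta is 0.82) while only ~6.7% has left the body by the first scan
at 4 h.  SUV magnitudes of the real study are figure-level quantities and
are deliberately not targets; orderings and trend directions are.

Imaging degradation: isotropic Gaussian blur (default σ = 4 mm, a PET-like
point-spread function) followed by voxelwise multiplicative Gaussian noise
(default CV = 0.03), negatives clipped, all seeded.  Blur conserves total
activity except for boundary truncation (< 0.5% for the interior-supported
body); the noise is uncorrelated, so whole-body sums self-average and the
recovery QC lands at ~6.7–6.8% deviation, within the ±10% acceptance band.
What passing these tests does **not** show: real reconstructed PET has
correlated noise, partial-volume bias at organ boundaries, scatter/attenuation
correction residuals and registration error; none of these are modeled.

## Dose engines

All engines consume a therapy-nuclide activity volume (Bq/mL) and a density
volume (g/cm³) on a shared grid and emit Gy/h with an explicit energy ledger
(W emitted / deposited / escaped) so conservation is assertable per method.

**Local.** `Ḋ = C·10⁶·E_charged/ρ·3600`; all charged energy in the source
voxel.  Justified because the ¹⁷⁷Lu β/conversion-electron range (~0.2–2 mm
in soft tissue) is below the 4 mm voxel size.  Photons are not transported
(ledgered as escaped).

**Photon transport model (kernel and MC).** Single interaction, water
cross-sections scaled by local density: a photon of energy E travels with
attenuation µ(E) = (µ/ρ)_water(E)·ρ, deposits the energy-absorption fraction
µ_en/µ at its first interaction, and the scattered remainder is tallied as
escape rather than re-transported.  This keeps the kernel and MC engines
estimating the same quantity, which the cross-validation test exploits; the
neglected scatter dose is second-order for ¹⁷⁷Lu (photons carry ~29 keV/decay
against 148 keV charged) and bounded by the ledger.  Attenuation data are a
standard evaluated water table (30 keV–1.25 MeV) interpolated log-log.

**Kernel.** The radial first-interaction kernel
`K(r) = y·E·µ_en·e^{−µr}/(4πr²)` is discretized onto the lattice by
supersampling (fine factor 4) and pair-averaging over uniform source/target
positions (separable triangular filter), with sub-cell midpoint integration
inside 32 mm and an inscribed-sphere/corner split for the singular central
cell — plain center-point evaluation underestimates the convex 1/r² near
field by several percent, which would show up directly in the MC
cross-check.  The kernel is truncated at 128 mm; the analytic tail and
scatter fraction are carried in the ledger, and the discretized kernel mass
agrees with the analytic integral to ≤ 1% (measured ~0.01%).  Convolution is
FFT-based on the per-voxel decay rate, divided by local voxel mass; the
attenuation medium is homogeneous water, so heterogeneous-density studies are
better served by the MC engine.  Deposits landing on zero-density voxels are
reclassified as escape.

**Monte Carlo.** Per activity-rich voxel (default: any nonzero voxel;
configurable as a fraction of the maximum) a fixed number of decays (default
8000) is split into 10 batches.  Photons are emitted isotropically from
uniform positions in the voxel; the free path is sampled in optical depth
and marched through the density grid in half-voxel steps with exact
back-interpolation of the crossing point (unbiased for piecewise-constant
density).  Scores are scaled by true decay rate over simulated decays, so
doubling the activity field doubles every tally bit-for-bit under a fixed
seed.  Batch spread gives the per-voxel relative standard error, which
follows the 1/√N law (quadrupling decays halves it); the absolute
uncertainty-at-8000-decays of any particular production code depends on its
variance structure and is not asserted here.  With no photon lines the MC
reduces exactly (bitwise) to the local engine.

Numerical cross-validation: on a 16³ uniform water phantom the MC and kernel
whole-volume means agree within 3 standard errors over seeds 1–5 at 2000
decays/voxel — a size chosen so statistical error dominates the residual
discretization difference between the two estimators.

## Time integration

Trapezoid over the frame times (4/24/48/73 h by default).  The head segment
(0 → 4 h) is unobserved: default `constant_backfill` (`Ḋ₁·t₁`, conservative
since activity is present from injection), alternative `zero_at_origin`
(`½Ḋ₁t₁`).  The tail beyond the last scan defaults to `physical_decay`
(`Ḋ_last/λ`), matching the observed post-73 h behavior where elimination is
dominated by physical decay; `none` drops it.  Both are flags so sensitivity
can be reported.  Sampling a pure exponential hourly recovers 1/λ to 0.1%;
with only the four scheduled frames the combined head/segment errors stay
inside 1% for decay-dominated curves (asserted via the closed-form
dose-coefficient oracle).  No parametric time-activity fitting is performed.

## ROI metrics and prescription

SUV uses the body-weight convention with the implicit 1 g/mL bridge between
activity-per-volume and activity-per-mass, so a uniform non-excreting
distribution at unit density scores exactly 1.  ROI statistics are means over
nearest-neighbor-resampled label maps on the first frame's grid (ROI-mean
SUVs, labeled as such — maxima are not computed).  Dose coefficients come
from frames normalized to 1 GBq administered therapy activity (scale
10⁹/A_injected on the decay-corrected field); the dose map records that
provenance and coefficient extraction refuses maps without it.

Prescription: `A = D_limit/c_binding`, default limit 3 Gy over the marrow
ROIs.  The default binding rule is `max_over_rois` (no marrow region may
exceed the limit — safety-conservative).  The bundled three-beagle
coefficient table is only consistent with the left-shoulder marrow having
been the binding ROI (its spine coefficients would imply > 3 Gy at the
recorded activities), so `named_roi:marrow_left_shoulder` ships as a
documented alternative policy; neither is asserted as the historical intent.
Projected doses are computed from the unrounded activity; activities are
reported to 3 decimals (GBq), doses to 2 (Gy), and absent organs render
as `-`.

## Problem sizes and determinism

Default analyses run on the 64×64×128 phantom with the local engine
(< 1 s end-to-end); MC validation uses 8³–16³ uniform phantoms at 500–8000
decays per voxel, sizes at which the statistical tests are sharp.  Every
stochastic component (phantom noise, MC transport) takes an explicit seed;
the pipeline is digest-reproducible under a fixed seed.

## Known limitations

- Phantom anatomy is primitive-shaped and motion-free; kinetics are
  two-compartment with fixed route splits.
- Photon physics is first-interaction only (no scatter dose, buildup,
  bremsstrahlung, or daughter chains); the kernel additionally assumes a
  homogeneous water attenuation medium.
- Registration is identity (synthetic frames share a grid); only resampling
  between grids is implemented, and DICOM RT structure sets are replaced by
  integer label maps.
- Charged-particle transport is local deposition; sub-voxel dose gradients
  near marrow/bone interfaces are not resolved.
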