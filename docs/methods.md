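# Methods

This note documents the models implemented in `voxtab`, the parameters
that matter, the design choices made where the design was genuinely
open, and what the synthetic test conditions do and do not show about
real tablets.

## Geometry model

A tablet is an ordered bottom-to-top stack of layers extruded from an
oval punch footprint. The "oval" outline is idealized as an **ellipse**
by default: the closed form πab/4 for a 21.5 × 10 mm punch gives
168.86 mm², which reproduces the reported compaction stresses of the
reference tablets within ~2% (26 kN → 154.0 MPa vs the reported 155;
21 kN → 124.4 vs 126–127). A **stadium** model (rectangle capped by two
half-discs, 193.54 mm² for the same punch) is available because "oval
punch" is genuinely ambiguous; the ellipse is the default since it
matches the reported stresses better. Ellipse perimeters use the
complete elliptic integral of the second kind, not an approximation.

Layer thickness is derived from mass, porosity, true density and the
cross-section, t = m/((1−ε)ρA), whenever not supplied; a supplied
thickness inconsistent with that identity by more than 1% is rejected.
The derived thicknesses are **flat-faced prism estimates**: measured
caliper thicknesses of real tablets include punch cup curvature, which
this package deliberately does not model. For the same reason the
absolute exposed-surface areas computed here (perimeter × thickness plus
uncontacted faces) are model estimates; where measured areas exist, only
their *ratios* (percent of the standalone control, rounded to whole
percent) are treated as reproducible quantities.

Units are fixed by the schema: mg, mm, g/cm³, kN, MPa.

## Voxelization

The tablet is rasterized at a cubic pitch (74 μm reference, giving a
≤ 293³ grid for the reference geometry) with a liquid margin around it.
Each voxel is a *pure* substance — bulk liquid, a pore, or one solid
component. Within a layer, voxels independently become pores with
probability ε, otherwise a component drawn with probability equal to its
solid volume fraction v_k = (X_k/ρ_k)/Σ(X_j/ρ_j). This matches target
porosity and composition in expectation (binomially, so to ±0.5
percentage points for layers of ≥10⁴ voxels) but places no granule-scale
structure: real granulated material is clustered, and granule-scale
clustering would be the first realism upgrade. Placement is
deterministic per seed (one spawned sub-seed per layer).

## Cellular automaton

The transition rules are this package's own design, written to realize
three mechanisms: capillary ingress through the pore network,
species-specific dissolution, and mechanical erosion, with an
impermeable inert separator. Per step, three synchronous phases on the
6-neighbor (von Neumann) lattice:

1. **Ingress.** A pore voxel with ≥1 liquid face-neighbor becomes liquid
   with its layer's ingress probability. The probabilities encode the
   measured relative capillary constants of the two granulates
   (ASA : MA ≈ 8.84 : 1.81): the faster layer gets 1.0 per wetted step,
   the slower one the measured ratio (≈0.205). With layer porosities of
   7–14% — below the simple-cubic site percolation threshold of ~0.3116,
   which `percolation_check` verifies by flood fill — the pore network
   does not span, so bulk imbibition is minor and removal is
   front-dominated. That is the regime the reference tablets were
   observed to be in.

2. **Dissolution.** A wetted soluble voxel loses one resistance unit per
   step; at zero it becomes liquid and its mass is credited to the
   release ledger. Insoluble voxels (MCC, magnesium stearate, PCL) never
   dissolve and never transmit liquid.

3. **Erosion.** A solid voxel with fewer than k solid face-neighbors and
   at least one liquid neighbor detaches (default k = 2, i.e. voxels
   held by ≤1 neighbor). Detached soluble material counts as released;
   detached insoluble material moves to a suspended-particles ledger and
   never appears in a release curve. An optional disintegrant-burst
   flag lets wetted croscarmellose convert instantly and force ingress
   into adjacent pores.

The update is double-buffered per phase (no scan-order bias). One
full-lattice random field is drawn per step from a counter-based Philox
stream regardless of state, so paired runs with a common seed see
identical randomness — this is what makes the bilayer/triple-layer
comparisons common-random-number paired. Mass ledgers are integer voxel
counts per species, so released + on-grid + detached = initial holds
*exactly* at every step, not to floating tolerance.

With ingress 1, resistance 1 and erosion off the automaton reduces to a
unit-speed erosion front; a W³ cube dissolves in exactly ⌈W/2⌉ steps,
which the tests verify against an independent set-enumeration oracle.

### Dissolution resistances are matrix constants

The per-voxel resistance is the **local mass-removal timescale of the
compacted matrix**, not the intrinsic dissolution rate of the raw
material. Defaults: 6 steps/voxel for every soluble component of the
ASA layer, 2 steps/voxel for the MA layer, infinite for insolubles.

Two observations force this parameterization:

* Mechanistically, the low-porosity ASA layer recedes by slow surface
  erosion over the whole dissolution window, while the thinner, more
  porous MA layer is disintegration-dominated and clears several times
  faster; once its granules detach they no longer obstruct liquid. A
  single per-voxel constant must therefore be *small* for the MA layer
  even though mefenamic acid itself is the poorly soluble compound.
* Numerically, ranking constants by intrinsic solubility instead (fast
  mannitol/croscarmellose at ~40% of the layer volume, slow API) makes
  the fast-dissolving fraction plus pores exceed the percolation
  threshold: liquid invades the whole layer through the excipient
  network within a few steps, dissolution becomes bulk-like, and all
  surface/geometry effects vanish. Real compacts avoid this through
  intra-porous saturation and viscosity (dissolved solute passivates
  transport), which the automaton does not model; the matrix-level
  constant is the effective substitute.

Solute feedback (saturation, viscosity passivation) and paddle
hydrodynamics are not modeled.

### Time calibration

The automaton's step has no intrinsic duration. `seconds_per_step`
defaults to 1 and `calibrate_seconds_per_step` fixes it by running a
reference tablet and rescaling so that a chosen species reaches a target
release at a target time. The calibration uses only the automaton
itself, never an experimental curve.

### Disintegration time

Defined as the first time at which less than 1% of the *initial soluble*
solid remains undissolved and undetached; an insoluble separator is
excluded from the criterion (a PCL slab legitimately persists). A
tablet that never reaches the criterion is reported as
not-disintegrated, with the run's final time.

## Noyes–Whitney fitting

The first-order law dC/dt = (D·S/h)(Cs − C) has the closed form
C(t) = Cs(1 − e^(−kt)), k = D·S/h. Only the product D·S/h is
identifiable, so D (7·10⁻⁶ cm²/s) and h (30 μm) are fixed,
literature-typical placeholder values, and S is the sole fitted
coefficient; any comparison of fitted surfaces is valid exactly when D,
h and Cs are shared, which `surface_reduction_ratio` enforces. For
complete-release formulations Cs is 100% of dose; sub-plateau behavior
is expressed by passing Cs < 100 explicitly.

The fit minimizes the sum of squared residuals over log₁₀S by bounded
scalar minimization (bracket 10⁻⁶–10⁸ cm²/g, tolerance 10⁻¹⁰),
deterministic and scale-insensitive. Degenerate inputs are rejected:
all-zero profiles (no signal) and profiles already at plateau over the
whole sampled window (S unidentifiable, formally infinite). Noise-free
synthetic profiles are recovered to better than 10⁻⁶ relative; under 1%
absolute Gaussian noise on 12 points the estimator is unbiased to <1%
with median r² > 0.99 across 200 replicates.

## f2 similarity

f2 = 50·log₁₀{[1 + (1/n)Σ(Rₜ−Tₜ)²]^(−½)·100} over n ≥ 3 aligned time
points; 100 for identical profiles, and for a uniform offset d the
closed form 50·log₁₀(100/√(1+d²)) holds for every n (82.53 at d = 2,
49.89 at d = 10 — just below the conventional 50 cut-off). Profiles on
different grids are linearly interpolated onto the union of their
sampling times restricted to the overlap. No 85%-release truncation is
applied by default (full simulated curves are compared); the regulatory
truncation convention is available as an option. Values outside
[0, 100] are tolerated as assay noise but flagged with a warning.

## Synthetic study conditions

`paper_formulations()` encodes the four reference dosage forms: layer
masses 1000/300/500 mg, API weight fraction 0.50 per API layer,
porosities 7.1% (ASA standalone), 7.4% (ASA in multilayers), 13.7% (MA
standalone), 11.1% (MA in multilayers) — both MA values are kept,
labeled by context, with no reconciliation invented. The PCL separator
is modeled as a dense (ε = 0) impermeable slab; its porosity is not
reported and a poreless slab is the cleanest realization of an
impermeable layer. True densities: ASA 1.3928 and PCL 1.1600 g/cm³
(measured); MA 1.30, d-mannitol 1.49, MCC 1.56, croscarmellose 1.59,
HPC 1.22, magnesium stearate 1.09 g/cm³ are literature-typical
placeholders. Every numeric field carries a provenance tag
(`paper` / `placeholder` / `model`), and a test asserts the tagging is
complete.

`noisy_profile` generates first-order curves with additive Gaussian
assay noise (default σ = 1% absolute, 5-minute sampling over one hour,
clipped to [0, 105]) as stand-ins for experimental release data that
exist only as figures. These stand-ins share the *shape family* of the
fitting model, so parameter-recovery results demonstrate estimator
correctness, not model adequacy for real curves (real profiles can be
slightly sigmoidal, which a single-exponential cannot produce).

`toy_tablets` builds miniature grids of all four forms at a default
scale of 40 voxels along the longest dimension (pitch ≈ 0.54 mm). The
scale was chosen so that every layer, including the separator slab,
spans several voxels while a full run takes well under a second; layer
thickness ratios are inherited from the full geometry. At this
resolution a voxel is ~7× the reference 74 μm pitch, so absolute front
speeds are coarse; the paired-seed comparisons (triple vs bilayer)
measure *rank order* and relative effect sizes, which are
resolution-stable, rather than absolute times. Full 293³ runs are
supported through the same API.

## Known limitations

* No granule-scale microstructure; per-voxel multinomial placement.
* No solute saturation/viscosity feedback; matrix-level resistances are
  the effective substitute (see above).
* Flat-faced prism geometry; punch cup curvature and therefore measured
  caliper thicknesses/absolute surface areas are out of scope.
* The MA-vs-ASA single-tablet disintegration *ordering* is not
  reproduced by the defaults (the matrix constants prioritize the
  multilayer release mechanism over single-tablet disintegration
  ranking); the multilayer orderings — bilayer slower than both singles,
  triple-layer slower than bilayer — are reproduced.
* Compaction mechanics, swelling pressure, and hydrodynamics of the
  dissolution apparatus are not modeled.
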