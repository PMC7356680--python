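# voxtab

Voxel cellular-automata simulation of disintegration and dissolution of
multilayer pharmaceutical tablets, with Noyes–Whitney release-curve
fitting and f2 dissolution-profile similarity analysis.

## The problem

Fixed-dose combination products are often built as bi- or triple-layer
tablets: each active pharmaceutical ingredient (API) gets its own layer,
and an inert separation layer may be inserted between them for chemical
stability. Counterintuitively, an *insoluble* separator (e.g. a
polycaprolactone slab) can markedly slow the release of a *highly
soluble* API in the adjacent layer — not by any chemical interaction,
but by occluding one face of that layer and removing dissolution contact
surface — while the release of the other, poorly soluble API is
unchanged. `voxtab` is for formulation scientists who want to explore
this class of geometry effects in silico: it simulates the coupled
disintegration/dissolution of layered compacts on a voxel lattice and
quantifies the resulting release kinetics.

The reference system is a mefenamic acid (MA) / acetylsalicylic acid
(ASA) combination compressed on a 21.5 × 10 mm oval punch: an ASA layer
(1000 mg, 50% ASA), an MA layer (500 mg, 50% MA), and, in the
triple-layer form, a 300 mg polycaprolactone (PCL) separator between
them.

## What it computes

**Geometry** (`voxtab.geometry`) — layer true density
ρ = 1/Σ(Xᵢ/ρᵢ), porosity ε = 1 − m/(Vρ), effective compressive stress
P = F·1000/S, elliptical/stadium cross-sections, and per-layer exposed
surface areas (a contacted face contributes zero).

**Voxelization** (`voxtab.voxelize`) — rasterizes a layered tablet onto
a cubic lattice (reference pitch 74 μm, grid ≤ 293³) and fills each
layer stochastically: a voxel becomes a pore with probability ε,
otherwise one solid component in proportion to its solid volume
fraction.

**Cellular automaton** (`voxtab.ca`) — a synchronous three-phase update
on the 6-neighbor lattice: (1) liquid ingress into wetted pores with a
per-layer probability set from measured capillary imbibition rates,
(2) dissolution of wetted soluble voxels after a species-specific number
of steps, (3) erosion of loosely held surface voxels. Insoluble
material never dissolves, never transmits liquid, and detaches into a
separate suspended-particles ledger. Mass is conserved exactly (integer
voxel ledgers), release curves are monotone, and runs are bit-for-bit
reproducible per seed.

**Kinetics** (`voxtab.kinetics`) — the Noyes–Whitney first-order law
dC/dt = (D·S/h)(Cs − C), fitted to a release profile with the specific
surface S as the *sole* free coefficient; the ratio of two fitted
surfaces measures how much dissolution contact area one geometry loses
relative to another.

**Similarity** (`voxtab.similarity`) — the f2 factor
f2 = 50·log₁₀{[1 + (1/n)Σ(Rₜ−Tₜ)²]^(−½)·100} between two profiles on an
aligned time grid; f2 > 50 is the conventional similarity cut-off.

**Fixtures** (`voxtab.synthetic`) — the four study dosage forms (MA
tablet, ASA tablet, bilayer, triple-layer) with printed masses,
fractions and porosities; noisy first-order release curves as synthetic
stand-ins for experimental data; miniature toy grids for fast
simulation.

## Worked example

```python
import numpy as np
import voxtab as vt

fx = vt.paper_formulations()
area = vt.cross_section_area(fx.triple_layer)
print(f"{area:.2f} mm^2")                     # 168.86  (ellipse 21.5 x 10 mm)
stress = vt.effective_compressive_stress(vt.StressInput(26.0, area))
print(f"{stress:.1f} MPa")                    # 154.0   (26 kN on that footprint)

# surface lost to the separator, from the measured areas
print(vt.surface_fraction_of_control(289.3, 350.2))   # 83  (MA layer, %)
print(vt.surface_fraction_of_control(318.4, 484.4))   # 66  (ASA layer, %)

# paired automaton runs on miniature tablets, common random numbers
toys = vt.toy_tablets(seed=0)
rules = fx.default_rules
rb = vt.simulate(toys["bilayer"], rules, seed=1)
rt = vt.simulate(toys["triple_layer"], rules, seed=1)
print(rb.time_to_release("ASA", 80), rb.disintegration_time)   # 20.0 28.0
print(rt.time_to_release("ASA", 80), rt.disintegration_time)   # 24.0 37.0
```

The triple-layer toy needs 24 s to release 80% of its ASA dose against
20 s for the bilayer, and disintegrates in 37 s against 28 s — the inert
slab slows the soluble lower layer — while the two MA curves remain
nearly identical (f2 ≈ 98). Fitting two synthetic profiles generated
with specific surfaces 0.45 and 0.25 cm²/g (1% assay noise) recovers

```text
S_ref = 0.4450 cm^2/g (r2=0.9952), S_test = 0.2497 (r2=0.9980)
surface reduction ratio = 1.782
```

i.e. a ~1.8-fold loss of dissolution contact surface, estimated from the
curves alone.

A command-line interface wraps the same pipeline:

```sh
voxtab fixtures-export --out-dir fixtures
voxtab build --config fixtures/triple_layer.yaml --pitch-um 300 --seed 1 --out grid
voxtab simulate --grid grid --seed 2 --out release.csv
voxtab compare release.csv other.csv
voxtab fit-and-compare ref.csv test.csv --species ASA
```

## Layout

```
src/voxtab/        geometry, voxelize, ca, kinetics, similarity, synthetic, io, cli
tests/             pytest suite (unit, property and end-to-end tests)
scripts/           acceptance.py
docs/methods.md    model assumptions, parameters, numerical choices, limitations
```
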