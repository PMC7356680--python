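"""Discretization of a layered tablet onto a cubic voxel lattice.

Each voxel is a pure substance: bulk liquid, a pore, or one solid
component.  Layers are filled stochastically so that the achieved pore
fraction matches the target porosity and the solid phase matches the
formulation's volume fractions.

Conventions: the z axis is the compression axis, layer 0 sits at low z,
voxel indices are 0-based, and the voxel edge length (pitch) is in
micrometres.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .geometry import Component, LayerSpec, TabletSpec

__all__ = [
    "LIQUID",
    "PORE",
    "UNASSIGNED",
    "FIRST_SPECIES_ID",
    "SpeciesInfo",
    "VoxelGrid",
    "voxelize",
    "assign_layer_components",
    "build_tablet_grid",
    "grid_summary",
    "save_grid",
    "load_grid",
]

# voxel state codes; solid species occupy FIRST_SPECIES_ID, FIRST_SPECIES_ID+1, ...
LIQUID = 0  # bulk medium; also the state a dissolved voxel takes
PORE = 1
UNASSIGNED = 2  # layer interior before component placement
FIRST_SPECIES_ID = 3

MAX_GRID_VOXELS = 512**3


@dataclass(frozen=True)
class SpeciesInfo:
    """A solid species: one component within one layer."""

    species_id: int
    component: Component
    layer_index: int
    layer_label: str


@dataclass
class VoxelGrid:
    """A cubic lattice of voxel states plus its species table.

    ``states`` holds one code per voxel (liquid, pore or species id);
    ``layers`` holds the layer index of each tablet voxel, -1 outside
    the tablet envelope.
    """

    pitch_um: float
    states: np.ndarray  # int16, shape (nx, ny, nz)
    layers: np.ndarray  # int8, same shape; -1 = exterior
    species_table: dict[int, SpeciesInfo]
    spec: TabletSpec | None = None
    seed: int | None = None

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.states.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.pitch_um * 1e-4) ** 3

    def layer_mask(self, layer_index: int) -> np.ndarray:
        return self.layers == layer_index

    def species_for_layer(self, layer_index: int) -> list[SpeciesInfo]:
        return [s for s in self.species_table.values() if s.layer_index == layer_index]

    def voxel_mass_mg(self, species_id: int) -> float:
        """Mass of one pure voxel of the given species, mg."""
        info = self.species_table[species_id]
        return self.voxel_volume_cm3 * info.component.true_density * 1000.0

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            pitch_um=self.pitch_um,
            states=self.states.copy(),
            layers=self.layers.copy(),
            species_table=dict(self.species_table),
            spec=self.spec,
            seed=self.seed,
        )


def _inside_outline(spec: TabletSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mask of (x, y) points (mm, punch-centered) inside the outline."""
    a, b = spec.punch_major_axis, spec.punch_minor_axis
    if spec.shape_model == "ellipse":
        return (x / (a / 2.0)) ** 2 + (y / (b / 2.0)) ** 2 <= 1.0
    # stadium: points within b/2 of the center segment of length a - b
    half_seg = (a - b) / 2.0
    dx = np.maximum(np.abs(x) - half_seg, 0.0)
    return dx**2 + y**2 <= (b / 2.0) ** 2


def voxelize(spec: TabletSpec, pitch_um: float = 74.0, margin_voxels: int = 2) -> VoxelGrid:
    """Rasterize a tablet onto a cubic grid of the given pitch.

    Voxel centers inside the oval prism of a layer receive that layer's
    index (state UNASSIGNED until components are placed); everything else
    is bulk liquid.  The grid extends ``margin_voxels`` of liquid beyond
    the tablet's bounding box on every side.
    """
    if pitch_um <= 0:
        raise ValidationError("pitch must be > 0")
    if margin_voxels < 0:
        raise ValidationError("margin_voxels must be >= 0")
    pitch_mm = pitch_um / 1000.0
    thicknesses = spec.layer_thicknesses_mm()
    extent = (spec.punch_major_axis, spec.punch_minor_axis, sum(thicknesses))
    dims = tuple(int(math.ceil(e / pitch_mm)) + 2 * margin_voxels for e in extent)
    if math.prod(dims) > MAX_GRID_VOXELS:
        raise ValidationError(
            f"grid {dims} exceeds the configured maximum of {MAX_GRID_VOXELS} voxels"
        )

    nx, ny, nz = dims
    # voxel-center coordinates, tablet centered at the origin in x, y
    # and starting at z = 0
    cx = (np.arange(nx) - margin_voxels + 0.5) * pitch_mm - extent[0] / 2.0
    cy = (np.arange(ny) - margin_voxels + 0.5) * pitch_mm - extent[1] / 2.0
    cz = (np.arange(nz) - margin_voxels + 0.5) * pitch_mm

    X, Y = np.meshgrid(cx, cy, indexing="ij")
    footprint = _inside_outline(spec, X, Y)

    layers = np.full(dims, -1, dtype=np.int8)
    z_lo = 0.0
    for i, t in enumerate(thicknesses):
        z_hi = z_lo + t
        in_z = (cz >= z_lo) & (cz < z_hi)
        if not in_z.any():
            warnings.warn(
                f"layer {spec.layers[i].label!r} is thinner than one voxel "
                f"at pitch {pitch_um} um and received zero voxels",
                stacklevel=2,
            )
        layers[footprint[:, :, None] & in_z[None, None, :]] = i
        z_lo = z_hi

    states = np.where(layers >= 0, UNASSIGNED, LIQUID).astype(np.int16)
    species_table: dict[int, SpeciesInfo] = {}
    next_id = FIRST_SPECIES_ID
    for i, layer in enumerate(spec.layers):
        for comp in layer.formulation:
            species_table[next_id] = SpeciesInfo(next_id, comp, i, layer.label)
            next_id += 1
    return VoxelGrid(pitch_um=pitch_um, states=states, layers=layers,
                     species_table=species_table, spec=spec)


def assign_layer_components(grid: VoxelGrid, layer_index: int, seed: int) -> VoxelGrid:
    """Fill one layer's voxels with pores and components, in place.

    Each voxel of the layer independently becomes a pore with probability
    equal to the target porosity, otherwise a solid species with
    probability proportional to its solid volume fraction.  Reproducible
    bit-for-bit for a given seed.
    """
    if grid.spec is None:
        raise ValidationError("grid has no tablet spec attached")
    layer = grid.spec.layers[layer_index]
    eps = layer.porosity
    if not 0.0 <= eps < 1.0:
        raise ValidationError("porosity must be in [0, 1)")
    mask = grid.layer_mask(layer_index)
    n = int(mask.sum())
    if n == 0:
        return grid

    species = sorted(grid.species_for_layer(layer_index), key=lambda s: s.species_id)
    vfracs = layer.formulation.solid_volume_fractions()
    ids = np.array([s.species_id for s in species], dtype=np.int16)
    probs = np.array([vfracs[s.component.name] for s in species])

    rng = np.random.default_rng(seed)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int16)
    pore = u < eps
    out[pore] = PORE
    # rescale the non-pore draws onto [0, 1) and pick a species by its
    # cumulative volume fraction
    v = (u[~pore] - eps) / (1.0 - eps)
    cum = np.cumsum(probs)
    cum[-1] = 1.0  # guard against round-off excluding the last species
    out[~pore] = ids[np.searchsorted(cum, v, side="right")]
    grid.states[mask] = out
    return grid


def build_tablet_grid(
    spec: TabletSpec,
    pitch_um: float = 74.0,
    margin_voxels: int = 2,
    seed: int = 0,
) -> VoxelGrid:
    """Voxelize a tablet and place components in every layer.

    Per-layer placement seeds are spawned from ``seed`` with a
    ``SeedSequence`` so the layers' streams are independent.
    """
    grid = voxelize(spec, pitch_um=pitch_um, margin_voxels=margin_voxels)
    children = np.random.SeedSequence(seed).spawn(len(spec.layers))
    for i in range(len(spec.layers)):
        layer_seed = int(children[i].generate_state(1)[0] % (2**31))
        assign_layer_components(grid, i, seed=layer_seed)
    grid.seed = seed
    return grid


def grid_summary(grid: VoxelGrid) -> dict:
    """Per-state voxel counts and per-layer achieved porosity."""
    states = grid.states
    counts = {
        "liquid": int((states == LIQUID).sum()),
        "pore": int((states == PORE).sum()),
        "unassigned": int((states == UNASSIGNED).sum()),
    }
    per_species = {
        int(sid): int((states == sid).sum()) for sid in grid.species_table
    }
    layer_porosity = {}
    n_layers = int(grid.layers.max()) + 1 if grid.layers.max() >= 0 else 0
    for i in range(n_layers):
        mask = grid.layer_mask(i)
        total = int(mask.sum())
        pores = int((states[mask] == PORE).sum())
        label = grid.spec.layers[i].label if grid.spec else str(i)
        layer_porosity[label] = pores / total if total else float("nan")
    total_voxels = int(np.prod(states.shape))
    assert counts["liquid"] + counts["pore"] + counts["unassigned"] + sum(
        per_species.values()
    ) == total_voxels
    return {
        "dims": grid.dims,
        "pitch_um": grid.pitch_um,
        "total_voxels": total_voxels,
        "state_counts": counts,
        "species_counts": per_species,
        "layer_porosity": layer_porosity,
    }


def save_grid(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as a compressed array container plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), states=grid.states, layers=grid.layers)
    sidecar = {
        "pitch_um": grid.pitch_um,
        "seed": grid.seed,
        "species_table": {
            str(sid): {
                "name": s.component.name,
                "true_density": s.component.true_density,
                "solubility_class": s.component.solubility_class.value,
                "dissolution_resistance": s.component.dissolution_resistance,
                "role": s.component.role.value,
                "weight_fraction": s.component.weight_fraction,
                "layer_index": s.layer_index,
                "layer_label": s.layer_label,
            }
            for sid, s in grid.species_table.items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_grid(path: str | Path) -> VoxelGrid:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    from .geometry import Role, SolubilityClass

    table = {}
    for sid, rec in sidecar["species_table"].items():
        comp = Component(
            name=rec["name"],
            weight_fraction=rec["weight_fraction"],
            true_density=rec["true_density"],
            solubility_class=SolubilityClass(rec["solubility_class"]),
            dissolution_resistance=rec["dissolution_resistance"],
            role=Role(rec["role"]),
        )
        table[int(sid)] = SpeciesInfo(int(sid), comp, rec["layer_index"], rec["layer_label"])
    return VoxelGrid(
        pitch_um=sidecar["pitch_um"],
        states=arrays["states"],
        layers=arrays["layers"],
        species_table=table,
        seed=sidecar.get("seed"),
    )
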