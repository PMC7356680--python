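"""Synchronous 3D cellular automaton for tablet disintegration/dissolution.

The automaton evolves a voxelized tablet immersed in liquid through three
phases per step, each synchronous over the whole lattice:

1. *Ingress* — a pore voxel with at least one liquid face-neighbor fills
   with liquid with a per-layer probability (a proxy for the layer's
   capillary imbibition rate).
2. *Dissolution* — a soluble solid voxel with at least one liquid
   face-neighbor loses one unit of its dissolution resistance; at zero it
   becomes liquid and its mass is credited to the release ledger.
   Insoluble voxels never dissolve and never transmit liquid.
3. *Erosion/detachment* — a solid voxel held by fewer than ``k`` solid
   face-neighbors and touching liquid detaches: soluble material counts
   as released, insoluble material is moved to a suspended-particles
   ledger and never appears in any release curve.

The neighborhood is the 6-face von Neumann stencil; the update is double
buffered within each phase, so there is no scan-order bias.  All random
draws come from one counter-based (Philox) stream and one full-lattice
random field is drawn every step regardless of state, which keeps paired
runs with common random numbers synchronized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .geometry import Role, SolubilityClass
from .voxelize import FIRST_SPECIES_ID, LIQUID, PORE, UNASSIGNED, VoxelGrid

__all__ = [
    "RuleSet",
    "CAState",
    "SimulationResult",
    "initialize",
    "step",
    "run",
    "simulate",
    "disintegration_time",
    "percolation_check",
    "calibrate_seconds_per_step",
]


@dataclass(frozen=True)
class RuleSet:
    """Transition parameters of the automaton.

    ``ingress_probability`` maps a layer label to the per-step probability
    that a wetted pore voxel of that layer fills with liquid; labels not
    listed fall back to ``default_ingress``.  ``dissolution_resistance``
    optionally overrides, by component name, the resistance stored on the
    components themselves.  ``detachment_threshold`` is the minimum number
    of solid face-neighbors a wetted solid voxel needs to stay attached
    (0 disables erosion).  ``seconds_per_step`` converts automaton steps
    to wall-clock seconds.
    """

    ingress_probability: dict[str, float] = field(default_factory=dict)
    default_ingress: float = 1.0
    dissolution_resistance: Optional[dict[str, int]] = None
    detachment_threshold: int = 0
    disintegrant_burst: bool = False
    seconds_per_step: float = 1.0

    def __post_init__(self) -> None:
        for label, p in self.ingress_probability.items():
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"ingress probability for layer {label!r} must be in (0, 1], got {p}"
                )
        if not 0.0 < self.default_ingress <= 1.0:
            raise ValidationError("default_ingress must be in (0, 1]")
        if self.detachment_threshold < 0:
            raise ValidationError("detachment_threshold must be >= 0")
        if self.seconds_per_step <= 0:
            raise ValidationError("seconds_per_step must be > 0")
        if self.dissolution_resistance:
            for name, r in self.dissolution_resistance.items():
                if r < 1:
                    raise ValidationError(
                        f"dissolution resistance for {name!r} must be >= 1"
                    )

    def ingress_for(self, layer_label: str) -> float:
        return self.ingress_probability.get(layer_label, self.default_ingress)

    def resistance_for(self, component) -> float:
        """Resistance in steps; infinite for insoluble components."""
        if component.solubility_class is SolubilityClass.INSOLUBLE:
            return math.inf
        if self.dissolution_resistance and component.name in self.dissolution_resistance:
            return float(self.dissolution_resistance[component.name])
        return float(component.dissolution_resistance)

    def with_seconds_per_step(self, seconds_per_step: float) -> "RuleSet":
        return RuleSet(
            ingress_probability=dict(self.ingress_probability),
            default_ingress=self.default_ingress,
            dissolution_resistance=(
                dict(self.dissolution_resistance)
                if self.dissolution_resistance
                else None
            ),
            detachment_threshold=self.detachment_threshold,
            disintegrant_burst=self.disintegrant_burst,
            seconds_per_step=seconds_per_step,
        )


@dataclass
class CAState:
    """Mutable automaton state.

    The mass ledger is kept in whole voxels per species, so the identity
    released + remaining + detached == initial holds exactly at every step.
    """

    grid: VoxelGrid
    rules: RuleSet
    counters: np.ndarray  # float32 remaining resistance per voxel; inf = insoluble
    initial_voxels: dict[int, int]
    released_voxels: dict[int, int]
    detached_voxels: dict[int, int]
    step_index: int
    rng: np.random.Generator
    # lookup tables indexed by state code
    _soluble_lut: np.ndarray
    _disintegrant_lut: np.ndarray
    _ingress_p: np.ndarray  # per-voxel ingress probability

    @property
    def states(self) -> np.ndarray:
        return self.grid.states

    def remaining_voxels(self, sid: int) -> int:
        return (
            self.initial_voxels[sid]
            - self.released_voxels[sid]
            - self.detached_voxels[sid]
        )

    def soluble_species(self) -> list[int]:
        return [
            sid
            for sid, info in self.grid.species_table.items()
            if info.component.is_soluble
        ]

    def soluble_remaining_fraction(self) -> float:
        """Fraction of the initial soluble voxel count still solid."""
        soluble = self.soluble_species()
        initial = sum(self.initial_voxels[s] for s in soluble)
        if initial == 0:
            return 0.0
        remaining = sum(self.remaining_voxels(s) for s in soluble)
        return remaining / initial

    def released_mass_mg(self) -> dict[str, float]:
        """Cumulative released mass per component name, mg."""
        out: dict[str, float] = {}
        for sid, n in self.released_voxels.items():
            name = self.grid.species_table[sid].component.name
            out[name] = out.get(name, 0.0) + n * self.grid.voxel_mass_mg(sid)
        return out

    def detached_insoluble_mass_mg(self) -> float:
        return sum(
            n * self.grid.voxel_mass_mg(sid)
            for sid, n in self.detached_voxels.items()
        )

    def api_release_pct(self) -> dict[str, float]:
        """Cumulative % of dose released for each API component."""
        out: dict[str, float] = {}
        by_name: dict[str, tuple[int, int]] = {}
        for sid, info in self.grid.species_table.items():
            if info.component.role is not Role.API:
                continue
            rel, ini = by_name.get(info.component.name, (0, 0))
            by_name[info.component.name] = (
                rel + self.released_voxels[sid],
                ini + self.initial_voxels[sid],
            )
        for name, (rel, ini) in by_name.items():
            out[name] = 100.0 * rel / ini if ini else 0.0
        return out


def _layer_labels(grid: VoxelGrid) -> list[str]:
    """Label of each layer, from the tablet spec or the species table."""
    n_layers = int(grid.layers.max()) + 1 if grid.layers.max() >= 0 else 0
    if grid.spec is not None:
        return [layer.label for layer in grid.spec.layers]
    labels = [str(i) for i in range(n_layers)]
    for info in grid.species_table.values():
        if 0 <= info.layer_index < n_layers:
            labels[info.layer_index] = info.layer_label
    return labels


def _face_neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Number of True face-neighbors per voxel (outside the array counts False)."""
    c = np.zeros(mask.shape, dtype=np.int8)
    c[1:, :, :] += mask[:-1, :, :]
    c[:-1, :, :] += mask[1:, :, :]
    c[:, 1:, :] += mask[:, :-1, :]
    c[:, :-1, :] += mask[:, 1:, :]
    c[:, :, 1:] += mask[:, :, :-1]
    c[:, :, :-1] += mask[:, :, 1:]
    return c


def initialize(grid: VoxelGrid, rules: RuleSet, seed: int = 0) -> CAState:
    """Set up the automaton: exterior liquid, full counters, empty ledgers."""
    if (grid.states == UNASSIGNED).any():
        raise ValidationError(
            "grid contains unassigned voxels; run assign_layer_components first"
        )
    states = grid.states
    max_id = max(grid.species_table, default=FIRST_SPECIES_ID - 1)

    soluble_lut = np.zeros(max_id + 1, dtype=bool)
    disintegrant_lut = np.zeros(max_id + 1, dtype=bool)
    resistance_lut = np.zeros(max_id + 1, dtype=np.float32)
    for sid, info in grid.species_table.items():
        soluble_lut[sid] = info.component.is_soluble
        disintegrant_lut[sid] = info.component.role is Role.DISINTEGRANT
        resistance_lut[sid] = rules.resistance_for(info.component)

    counters = np.zeros(states.shape, dtype=np.float32)
    solid = states >= FIRST_SPECIES_ID
    counters[solid] = resistance_lut[states[solid]]

    labels = _layer_labels(grid)
    n_layers = len(labels)
    layer_p = np.ones(n_layers + 1, dtype=np.float64)
    for i, label in enumerate(labels):
        layer_p[i] = rules.ingress_for(label)
    # layers == -1 indexes the trailing slot; its value is never used
    # because exterior voxels are liquid already
    ingress_p = layer_p[grid.layers]

    initial = {
        int(sid): int((states == sid).sum()) for sid in grid.species_table
    }
    return CAState(
        grid=grid.copy(),
        rules=rules,
        counters=counters,
        initial_voxels=initial,
        released_voxels={sid: 0 for sid in initial},
        detached_voxels={sid: 0 for sid in initial},
        step_index=0,
        rng=np.random.Generator(np.random.Philox(key=seed)),
        _soluble_lut=soluble_lut,
        _disintegrant_lut=disintegrant_lut,
        _ingress_p=ingress_p,
    )


def _credit(ledger: dict[int, int], states: np.ndarray, mask: np.ndarray) -> None:
    if not mask.any():
        return
    sids, counts = np.unique(states[mask], return_counts=True)
    for sid, n in zip(sids, counts):
        ledger[int(sid)] += int(n)


def step(state: CAState) -> CAState:
    """Advance the automaton one step (in place); returns the state."""
    s = state.states
    rules = state.rules
    # one full-lattice field per step, independent of configuration
    r = state.rng.random(s.shape)

    solid = s >= FIRST_SPECIES_ID
    soluble = np.zeros_like(solid)
    soluble[solid] = state._soluble_lut[s[solid]]

    # --- phase 1: liquid ingress into wetted pores -----------------------
    liquid = s == LIQUID
    n_liq = _face_neighbor_count(liquid)
    pores = s == PORE
    wet_pores = pores & (n_liq > 0)
    fill = wet_pores & (r < state._ingress_p)
    if rules.disintegrant_burst:
        disint = np.zeros_like(solid)
        disint[solid] = state._disintegrant_lut[s[solid]]
        wet_disint = disint & (n_liq > 0)
        if wet_disint.any():
            # a bursting disintegrant forces ingress in adjacent pores
            fill |= wet_pores & (_face_neighbor_count(wet_disint) > 0)
    s[fill] = LIQUID

    # --- phase 2: dissolution of wetted soluble solids -------------------
    liquid = s == LIQUID
    n_liq = _face_neighbor_count(liquid)
    wet_solid = soluble & (n_liq > 0)
    state.counters[wet_solid] -= 1.0
    if rules.disintegrant_burst:
        burst = wet_solid & disint
        state.counters[burst] = 0.0
    dissolved = wet_solid & (state.counters <= 0.0)
    _credit(state.released_voxels, s, dissolved)
    s[dissolved] = LIQUID

    # --- phase 3: erosion / mechanical detachment ------------------------
    k = rules.detachment_threshold
    if k > 0:
        solid = s >= FIRST_SPECIES_ID
        liquid = s == LIQUID
        n_solid = _face_neighbor_count(solid)
        n_liq = _face_neighbor_count(liquid)
        loose = solid & (n_solid < k) & (n_liq > 0)
        if loose.any():
            loose_soluble = np.zeros_like(loose)
            loose_soluble[loose] = state._soluble_lut[s[loose]]
            _credit(state.released_voxels, s, loose & loose_soluble)
            _credit(state.detached_voxels, s, loose & ~loose_soluble)
            s[loose] = LIQUID

    state.step_index += 1
    return state


@dataclass
class SimulationResult:
    """Release curves and disintegration summary of one automaton run."""

    times: np.ndarray  # seconds, shape (n_records,)
    release_pct: dict[str, np.ndarray]  # per-API cumulative % of dose
    disintegration_time: Optional[float]  # None if never disintegrated
    disintegrated: bool
    completion_step: Optional[int]  # step at which all soluble solid was gone
    steps_run: int
    seconds_per_step: float
    final_summary: dict

    def time_to_release(self, species: str, pct: float) -> Optional[float]:
        """First recorded time at which a species' release reaches ``pct``."""
        curve = self.release_pct[species]
        idx = np.argmax(curve >= pct)
        if curve[idx] < pct:
            return None
        return float(self.times[idx])


def run(
    state: CAState,
    max_steps: int = 10_000,
    record_interval: int = 1,
) -> SimulationResult:
    """Step the automaton until all soluble solid is gone or ``max_steps``.

    The mass ledger identity (released + remaining + detached == initial,
    per species) is asserted at every recording point.
    """
    soluble_ids = state.soluble_species()
    initial_soluble = sum(state.initial_voxels[sid] for sid in soluble_ids)

    times = [state.step_index * state.rules.seconds_per_step]
    api_names = sorted(state.api_release_pct())
    curves: dict[str, list[float]] = {name: [state.api_release_pct()[name]] for name in api_names}

    disintegration_step: Optional[int] = None
    completion_step: Optional[int] = None
    if initial_soluble == 0:
        # nothing can dissolve: the run ends immediately and the tablet
        # is reported as never disintegrating
        completion_step = 0

    def record() -> None:
        times.append(state.step_index * state.rules.seconds_per_step)
        pct = state.api_release_pct()
        for name in api_names:
            curves[name].append(pct[name])
        for sid in state.initial_voxels:
            assert (
                state.released_voxels[sid]
                + state.remaining_voxels(sid)
                + state.detached_voxels[sid]
                == state.initial_voxels[sid]
            )

    while completion_step is None and state.step_index < max_steps:
        step(state)
        remaining = sum(state.remaining_voxels(sid) for sid in soluble_ids)
        if disintegration_step is None and remaining < 0.01 * initial_soluble:
            disintegration_step = state.step_index
        if remaining == 0:
            completion_step = state.step_index
        if state.step_index % record_interval == 0 or completion_step is not None:
            record()

    if completion_step is None and state.step_index >= max_steps:
        import warnings

        warnings.warn(
            f"automaton did not terminate within {max_steps} steps; "
            "release curves are truncated",
            stacklevel=2,
        )
        if times[-1] != state.step_index * state.rules.seconds_per_step:
            record()

    sps = state.rules.seconds_per_step
    disintegrated = disintegration_step is not None
    return SimulationResult(
        times=np.asarray(times, dtype=float),
        release_pct={name: np.asarray(c) for name, c in curves.items()},
        disintegration_time=(
            disintegration_step * sps if disintegrated else None
        ),
        disintegrated=disintegrated,
        completion_step=completion_step,
        steps_run=state.step_index,
        seconds_per_step=sps,
        final_summary={
            "released_mass_mg": state.released_mass_mg(),
            "detached_insoluble_mass_mg": state.detached_insoluble_mass_mg(),
            "soluble_remaining_fraction": state.soluble_remaining_fraction(),
        },
    )


def simulate(
    grid: VoxelGrid,
    rules: RuleSet,
    seed: int = 0,
    max_steps: int = 10_000,
    record_interval: int = 1,
) -> SimulationResult:
    """Convenience wrapper: initialize then run."""
    return run(
        initialize(grid, rules, seed=seed),
        max_steps=max_steps,
        record_interval=record_interval,
    )


def disintegration_time(result: SimulationResult) -> float:
    """Simulated disintegration time in seconds.

    Defined as the first time at which less than 1% of the initial
    soluble solid remains undissolved and undetached (an insoluble
    separator is excluded from the criterion).  If the tablet never
    disintegrates the run's final time is returned and
    ``result.disintegrated`` is False.
    """
    if result.disintegration_time is None:
        return float(result.steps_run * result.seconds_per_step)
    return result.disintegration_time


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def percolation_check(grid: VoxelGrid, layer_label: str) -> bool:
    """Does the pore network of a layer span from a face to its mid-plane?

    True iff a face-connected path of pore voxels links a liquid-wetted
    pore on the layer's bottom or top voxel slab to the layer's central
    z slab — i.e. liquid can imbibe half-way through the compact's depth
    without dissolving anything.  Porosities below the simple-cubic site
    percolation threshold (~0.312) fail this check with high probability.
    """
    labels = _layer_labels(grid)
    if layer_label not in labels:
        raise ValidationError(f"unknown layer {layer_label!r}; have {labels}")
    layer_index = labels.index(layer_label)
    in_layer = grid.layer_mask(layer_index)
    pores = (grid.states == PORE) & in_layer
    if not pores.any():
        return False

    zs = np.nonzero(in_layer.any(axis=(0, 1)))[0]
    mid_z = int(zs[len(zs) // 2])
    liquid = grid.states == LIQUID
    wetted = pores & (_face_neighbor_count(liquid) > 0)
    surface_pores = np.zeros_like(wetted)
    for z_face in (int(zs[0]), int(zs[-1])):
        surface_pores[:, :, z_face] = wetted[:, :, z_face]
    if not surface_pores.any():
        return False

    comp, _ = ndimage.label(pores, structure=_FACE_STRUCTURE)
    seed_labels = np.unique(comp[surface_pores])
    seed_labels = seed_labels[seed_labels > 0]
    mid_labels = np.unique(comp[:, :, mid_z][pores[:, :, mid_z]])
    return bool(np.intersect1d(seed_labels, mid_labels).size > 0)


def calibrate_seconds_per_step(
    grid: VoxelGrid,
    rules: RuleSet,
    target_time_s: float,
    target_release_pct: float = 80.0,
    reference_species: Optional[str] = None,
    seed: int = 0,
    max_steps: int = 10_000,
) -> RuleSet:
    """Fix the step-to-seconds mapping against a reference tablet.

    Runs the automaton on ``grid`` with ``seconds_per_step = 1`` and
    rescales so that the reference species reaches ``target_release_pct``
    at ``target_time_s``.  The calibrated rule set is returned; the
    procedure uses only the automaton itself, no experimental curve.
    """
    probe = rules.with_seconds_per_step(1.0)
    result = simulate(grid, probe, seed=seed, max_steps=max_steps)
    if reference_species is None:
        reference_species = sorted(result.release_pct)[0]
    t = result.time_to_release(reference_species, target_release_pct)
    if t is None or t <= 0:
        raise ValidationError(
            f"reference run never reached {target_release_pct}% release "
            f"of {reference_species!r}; cannot calibrate"
        )
    return rules.with_seconds_per_step(target_time_s / t)
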