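"""Study fixtures and synthetic inputs.

Builds the four dosage forms of the study — a mefenamic acid (MA)
tablet, an acetylsalicylic acid (ASA) tablet, an ASA/MA bilayer, and a
triple-layer tablet with an insoluble polycaprolactone (PCL) separator —
from their printed compositions, masses and porosities; generates noisy
first-order release curves to stand in for experimental profiles that
are otherwise available only as figures; and produces miniature voxel
grids of the same architectures for fast simulation.

Every numeric field carries a provenance tag: ``paper`` for values taken
from the study's printed tables, ``placeholder`` for literature-typical
values the study does not print (some excipient true densities), and
``model`` for parameters of this package's own automaton rule set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ca import RuleSet
from .errors import ValidationError
from .geometry import (
    Component,
    Formulation,
    LayerSpec,
    Role,
    SolubilityClass,
    TabletSpec,
)
from .kinetics import NWParams, ReleaseProfile, nw_release
from .voxelize import (
    FIRST_SPECIES_ID,
    LIQUID,
    PORE,
    SpeciesInfo,
    VoxelGrid,
    build_tablet_grid,
)

__all__ = [
    "FixtureSet",
    "paper_formulations",
    "default_rules",
    "noisy_profile",
    "toy_tablets",
    "uniform_block",
    "PROVENANCE_PAPER",
    "PROVENANCE_PLACEHOLDER",
    "PROVENANCE_MODEL",
]

PROVENANCE_PAPER = "paper"
PROVENANCE_PLACEHOLDER = "placeholder"
PROVENANCE_MODEL = "model"

# True densities, g/cm^3.  ASA and PCL were measured by helium pycnometry
# in the study; the rest are literature-typical crystal/bulk values.
_DENSITIES: dict[str, tuple[float, str]] = {
    "ASA": (1.3928, PROVENANCE_PAPER),
    "PCL": (1.1600, PROVENANCE_PAPER),
    "MA": (1.30, PROVENANCE_PLACEHOLDER),
    "d-mannitol": (1.49, PROVENANCE_PLACEHOLDER),
    "MCC": (1.56, PROVENANCE_PLACEHOLDER),
    "croscarmellose": (1.59, PROVENANCE_PLACEHOLDER),
    "HPC": (1.22, PROVENANCE_PLACEHOLDER),
    "MgSt": (1.09, PROVENANCE_PLACEHOLDER),
}

# Layer matrix removal constants, in automaton steps per voxel.  The
# per-voxel resistance expresses the local mass-removal timescale of the
# compacted matrix, not the intrinsic solubility of the raw material.
# The low-porosity ASA layer recedes by slow surface erosion over the
# whole dissolution window, whereas the thinner, more porous MA layer is
# disintegration-dominated and clears several times faster, after which
# its detached granules no longer obstruct liquid.  Model parameters of
# this package.
ASA_MATRIX_RESISTANCE = 6
MA_MATRIX_RESISTANCE = 2

ASA_LAYER_LABEL = "ASA layer"
MA_LAYER_LABEL = "MA layer"
PCL_LAYER_LABEL = "PCL separator"


def _component(name, fraction, solubility, role, resistance=1) -> Component:
    density, _ = _DENSITIES[name]
    return Component(
        name=name,
        weight_fraction=fraction,
        true_density=density,
        solubility_class=solubility,
        dissolution_resistance=resistance,
        role=role,
    )


def _api_layer_formulation(
    api: str, api_solubility: SolubilityClass, matrix_resistance: int
) -> Formulation:
    """Granule + external phase of an API layer, as weight fractions.

    Croscarmellose appears both intra-granularly (2%) and in the external
    phase (1%); the two portions are merged into one 3% component because
    the voxel model does not resolve granule boundaries.  All soluble
    components of a layer share that layer's matrix removal constant:
    in a compact the local removal rate is set by the matrix, not by the
    raw materials' intrinsic dissolution rates.
    """
    r = matrix_resistance
    return Formulation(
        [
            _component(api, 0.50, api_solubility, Role.API, r),
            _component("d-mannitol", 0.33, SolubilityClass.SOLUBLE, Role.DILUENT, r),
            _component("MCC", 0.10, SolubilityClass.INSOLUBLE, Role.DILUENT, r),
            _component("croscarmellose", 0.03, SolubilityClass.SOLUBLE, Role.DISINTEGRANT, r),
            _component("HPC", 0.03, SolubilityClass.SOLUBLE, Role.BINDER, r),
            _component("MgSt", 0.01, SolubilityClass.INSOLUBLE, Role.LUBRICANT, r),
        ]
    )


def _pcl_formulation() -> Formulation:
    return Formulation(
        [
            _component("PCL", 1.0, SolubilityClass.INSOLUBLE, Role.INERT_SEPARATOR),
        ]
    )


# printed layer masses (mg) and porosities (v/v fraction); the MA layer is
# 13.7% porous as a standalone tablet but 11.1% within the multilayer
# compacts, and the ASA layer 7.1% standalone vs 7.4% in multilayers
ASA_LAYER_MASS_MG = 1000.0
MA_LAYER_MASS_MG = 500.0
PCL_LAYER_MASS_MG = 300.0
ASA_POROSITY_SINGLE = 0.071
ASA_POROSITY_MULTILAYER = 0.074
MA_POROSITY_SINGLE = 0.137
MA_POROSITY_MULTILAYER = 0.111
PCL_POROSITY = 0.0  # dense impermeable slab; not printed in the study

PUNCH_MAJOR_MM = 21.5
PUNCH_MINOR_MM = 10.0

# relative liquid-imbibition rates of the two granulates, from the
# printed capillary constants (ASA 8.84e-6 vs MA 1.81e-6): the faster
# layer gets ingress probability 1 per wetted step, the slower one the
# measured ratio
CAPILLARY_CONSTANT_ASA = 8.84e-6
CAPILLARY_CONSTANT_MA = 1.81e-6


@dataclass
class FixtureSet:
    """The study's four dosage forms plus the default automaton rules."""

    ma_tablet: TabletSpec
    asa_tablet: TabletSpec
    bilayer: TabletSpec
    triple_layer: TabletSpec
    default_rules: RuleSet
    provenance: dict[str, str] = field(default_factory=dict)

    def tablets(self) -> dict[str, TabletSpec]:
        return {
            "ma_tablet": self.ma_tablet,
            "asa_tablet": self.asa_tablet,
            "bilayer": self.bilayer,
            "triple_layer": self.triple_layer,
        }


def default_rules() -> RuleSet:
    """Automaton rules for the study tablets.

    Ingress probabilities follow the measured capillary-constant ratio of
    the two granulates; erosion detaches voxels held by fewer than two
    solid neighbors; wetted disintegrant bursts.  ``seconds_per_step`` is
    left at 1 and is meant to be fixed with
    :func:`voxtab.ca.calibrate_seconds_per_step`.
    """
    return RuleSet(
        ingress_probability={
            ASA_LAYER_LABEL: 1.0,
            MA_LAYER_LABEL: CAPILLARY_CONSTANT_MA / CAPILLARY_CONSTANT_ASA,
            PCL_LAYER_LABEL: 1e-6,  # moot: the separator has no pores
        },
        default_ingress=1.0,
        detachment_threshold=2,
        disintegrant_burst=True,
        seconds_per_step=1.0,
    )


def paper_formulations() -> FixtureSet:
    """Build the four study dosage forms with provenance metadata."""
    asa_single = LayerSpec(
        formulation=_api_layer_formulation("ASA", SolubilityClass.SOLUBLE, ASA_MATRIX_RESISTANCE),
        mass_mg=ASA_LAYER_MASS_MG,
        porosity=ASA_POROSITY_SINGLE,
        label=ASA_LAYER_LABEL,
    )
    asa_multi = LayerSpec(
        formulation=_api_layer_formulation("ASA", SolubilityClass.SOLUBLE, ASA_MATRIX_RESISTANCE),
        mass_mg=ASA_LAYER_MASS_MG,
        porosity=ASA_POROSITY_MULTILAYER,
        label=ASA_LAYER_LABEL,
    )
    ma_single = LayerSpec(
        formulation=_api_layer_formulation("MA", SolubilityClass.SPARINGLY_SOLUBLE, MA_MATRIX_RESISTANCE),
        mass_mg=MA_LAYER_MASS_MG,
        porosity=MA_POROSITY_SINGLE,
        label=MA_LAYER_LABEL,
    )
    ma_multi = LayerSpec(
        formulation=_api_layer_formulation("MA", SolubilityClass.SPARINGLY_SOLUBLE, MA_MATRIX_RESISTANCE),
        mass_mg=MA_LAYER_MASS_MG,
        porosity=MA_POROSITY_MULTILAYER,
        label=MA_LAYER_LABEL,
    )
    pcl = LayerSpec(
        formulation=_pcl_formulation(),
        mass_mg=PCL_LAYER_MASS_MG,
        porosity=PCL_POROSITY,
        label=PCL_LAYER_LABEL,
    )

    def tablet(name: str, layers: list[LayerSpec]) -> TabletSpec:
        return TabletSpec(
            layers=layers,
            punch_major_axis=PUNCH_MAJOR_MM,
            punch_minor_axis=PUNCH_MINOR_MM,
            shape_model="ellipse",
            name=name,
        )

    provenance: dict[str, str] = {}
    for name, (_, tag) in _DENSITIES.items():
        provenance[f"true_density:{name}"] = tag
    for api in ("ASA", "MA"):
        for comp in ("ASA/MA", "d-mannitol", "MCC", "croscarmellose", "HPC", "MgSt"):
            provenance[f"weight_fraction:{api} layer:{comp}"] = PROVENANCE_PAPER
    provenance.update(
        {
            "mass:ASA layer": PROVENANCE_PAPER,
            "mass:MA layer": PROVENANCE_PAPER,
            "mass:PCL separator": PROVENANCE_PAPER,
            "porosity:ASA layer (single)": PROVENANCE_PAPER,
            "porosity:ASA layer (multilayer)": PROVENANCE_PAPER,
            "porosity:MA layer (single)": PROVENANCE_PAPER,
            "porosity:MA layer (multilayer)": PROVENANCE_PAPER,
            "porosity:PCL separator": PROVENANCE_PLACEHOLDER,
            "punch_major_axis": PROVENANCE_PAPER,
            "punch_minor_axis": PROVENANCE_PAPER,
            "ingress_probability:ASA layer": PROVENANCE_MODEL,
            "ingress_probability:MA layer": PROVENANCE_PAPER,  # measured ratio
            "ingress_probability:PCL separator": PROVENANCE_MODEL,
            "dissolution_resistance:*": PROVENANCE_MODEL,
            "detachment_threshold": PROVENANCE_MODEL,
            "seconds_per_step": PROVENANCE_MODEL,
        }
    )

    # layer order bottom-to-top: ASA, (PCL), MA — the ASA layer was the
    # first compacted layer and MA the top one
    return FixtureSet(
        ma_tablet=tablet("ma_tablet", [ma_single]),
        asa_tablet=tablet("asa_tablet", [asa_single]),
        bilayer=tablet("bilayer", [asa_multi, ma_multi]),
        triple_layer=tablet("triple_layer", [asa_multi, pcl, ma_multi]),
        default_rules=default_rules(),
        provenance=provenance,
    )


def noisy_profile(
    params: NWParams,
    times: np.ndarray,
    sigma_abs: float = 1.0,
    seed: int = 0,
    species: str = "",
) -> ReleaseProfile:
    """First-order release curve with additive Gaussian assay noise.

    Noise is independent per time point with absolute standard deviation
    ``sigma_abs`` (% of dose); values are clipped to [0, 105] as a real
    assay would report them.  Deterministic per seed.
    """
    if sigma_abs < 0:
        raise ValidationError("sigma_abs must be >= 0")
    times = np.asarray(times, dtype=float)
    clean = nw_release(times, params)
    if sigma_abs > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, sigma_abs, size=times.shape)
    return ReleaseProfile(times, np.clip(clean, 0.0, 105.0), species=species)


# default sampling mirrors the assay cadence of the study: every 5 min
# over one hour
DEFAULT_SAMPLING_S = np.arange(300.0, 3601.0, 300.0)
DEFAULT_NOISE_SIGMA = 1.0


def toy_tablets(scale: int = 40, seed: int = 0) -> dict[str, VoxelGrid]:
    """Miniature voxel grids of the four dosage forms.

    The voxel pitch is chosen so the longest tablet dimension spans
    ``scale`` voxels; layer-thickness ratios are inherited from the real
    geometry (the MA layer is roughly half as thick as the ASA layer).
    The default of 40 keeps every layer at least four voxels thick while
    a full automaton run stays well under a second.  Intended for fast
    simulation; ``scale`` is capped at 50.
    """
    if not 4 <= scale <= 50:
        raise ValidationError("scale must be in [4, 50]")
    fixtures = paper_formulations()
    grids: dict[str, VoxelGrid] = {}
    for name, spec in fixtures.tablets().items():
        extent = max(spec.punch_major_axis, spec.punch_minor_axis, spec.total_thickness_mm)
        pitch_um = extent / scale * 1000.0
        grids[name] = build_tablet_grid(spec, pitch_um=pitch_um, margin_voxels=2, seed=seed)
    return grids


def uniform_block(
    shape: tuple[int, int, int],
    component: Component,
    porosity: float = 0.0,
    margin: int = 1,
    seed: int = 0,
    label: str = "block",
) -> VoxelGrid:
    """A rectangular block of one component surrounded by liquid.

    A minimal grid for automaton unit tests and oracles (no tablet spec
    attached); with ``porosity`` > 0 pores are placed independently per
    voxel.
    """
    nx, ny, nz = (d + 2 * margin for d in shape)
    states = np.full((nx, ny, nz), LIQUID, dtype=np.int16)
    layers = np.full((nx, ny, nz), -1, dtype=np.int8)
    sl = tuple(slice(margin, margin + d) for d in shape)
    sid = FIRST_SPECIES_ID
    if porosity > 0.0:
        rng = np.random.default_rng(seed)
        block = np.where(
            rng.random(shape) < porosity, PORE, sid
        ).astype(np.int16)
        states[sl] = block
    else:
        states[sl] = sid
    layers[sl] = 0
    table = {sid: SpeciesInfo(sid, component, 0, label)}
    return VoxelGrid(
        pitch_um=100.0, states=states, layers=layers,
        species_table=table, spec=None, seed=seed,
    )
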