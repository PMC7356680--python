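"""Formulation and layered-tablet geometry.

Layer true density, porosity, effective compressive stress, punch
cross-sections and exposed surface areas for oval multilayer tablets.

Units are fixed throughout the package: masses in mg, lengths in mm,
densities in g/cm^3, forces in kN, stresses in MPa, areas in mm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from scipy.special import ellipe

from .errors import InconsistentGeometryError, ValidationError

__all__ = [
    "SolubilityClass",
    "Role",
    "Component",
    "Formulation",
    "LayerSpec",
    "TabletSpec",
    "StressInput",
    "layer_true_density",
    "layer_porosity",
    "effective_compressive_stress",
    "cross_section_area",
    "perimeter",
    "exposed_surface_area",
    "surface_fraction_of_control",
]


class SolubilityClass(str, Enum):
    SOLUBLE = "soluble"
    SPARINGLY_SOLUBLE = "sparingly_soluble"
    INSOLUBLE = "insoluble"


class Role(str, Enum):
    API = "api"
    DILUENT = "diluent"
    DISINTEGRANT = "disintegrant"
    BINDER = "binder"
    LUBRICANT = "lubricant"
    INERT_SEPARATOR = "inert_separator"


@dataclass(frozen=True)
class Component:
    """One raw material in a layer formulation.

    ``dissolution_resistance`` is the number of automaton steps a fully
    wetted voxel of this material survives before dissolving; insoluble
    materials are treated as having infinite resistance regardless of the
    stored integer.
    """

    name: str
    weight_fraction: float
    true_density: float
    solubility_class: SolubilityClass = SolubilityClass.SOLUBLE
    dissolution_resistance: int = 1
    role: Role = Role.DILUENT

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_fraction <= 1.0:
            raise ValidationError(
                f"weight_fraction of {self.name!r} must be in [0, 1], "
                f"got {self.weight_fraction}"
            )
        if self.true_density <= 0:
            raise ValidationError(f"true_density of {self.name!r} must be > 0")
        if self.dissolution_resistance < 1:
            raise ValidationError(
                f"dissolution_resistance of {self.name!r} must be >= 1"
            )

    @property
    def is_soluble(self) -> bool:
        return self.solubility_class is not SolubilityClass.INSOLUBLE

    @property
    def effective_resistance(self) -> float:
        """Resistance in steps; infinite for insoluble materials."""
        if not self.is_soluble:
            return math.inf
        return float(self.dissolution_resistance)


@dataclass(frozen=True)
class Formulation:
    """An ordered set of components whose weight fractions sum to one."""

    components: tuple[Component, ...]

    def __init__(self, components: Sequence[Component]):
        object.__setattr__(self, "components", tuple(components))
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValidationError(f"component names must be unique, got {names}")
        total = sum(c.weight_fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"weight fractions must sum to 1 (got {total!r})"
            )

    def __iter__(self):
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def true_density(self) -> float:
        return layer_true_density(self)

    def solid_volume_fractions(self) -> dict[str, float]:
        """Volume fraction of the solid phase occupied by each component."""
        specific = {c.name: c.weight_fraction / c.true_density for c in self}
        total = sum(specific.values())
        return {name: v / total for name, v in specific.items()}


def layer_true_density(formulation: Formulation) -> float:
    """True (pore-free) density of a layer, g/cm^3.

    Harmonic mean of component densities weighted by mass fraction:
    rho_layer = 1 / sum_i(X_i / rho_i).
    """
    return 1.0 / sum(c.weight_fraction / c.true_density for c in formulation)


def layer_porosity(mass_mg: float, volume_cm3: float, true_density: float) -> float:
    """Void fraction eps = 1 - m / (V * rho) of a compacted layer.

    Parameters are the layer mass (mg), its envelope volume (cm^3) and the
    true density of the solid (g/cm^3).  A negative result means the stated
    mass cannot fit in the stated volume and is rejected.
    """
    if mass_mg <= 0 or volume_cm3 <= 0 or true_density <= 0:
        raise ValidationError("mass, volume and true density must all be > 0")
    eps = 1.0 - (mass_mg / 1000.0) / (volume_cm3 * true_density)
    if eps < 0:
        raise InconsistentGeometryError(
            f"mass {mass_mg} mg exceeds solid capacity of {volume_cm3} cm^3 "
            f"at true density {true_density} g/cm^3 (porosity {eps:.4f})"
        )
    if eps >= 1:
        raise ValidationError("porosity >= 1: layer contains no solid")
    return eps


@dataclass(frozen=True)
class StressInput:
    """Compaction force (kN) and tablet cross-section (mm^2)."""

    compressive_force: float
    cross_section_area: float

    def __post_init__(self) -> None:
        if self.compressive_force <= 0:
            raise ValidationError("compressive_force must be > 0")
        if self.cross_section_area <= 0:
            raise ValidationError("cross_section_area must be > 0")


def effective_compressive_stress(inp: StressInput) -> float:
    """Compaction pressure P = F * 1000 / S in MPa (F in kN, S in mm^2)."""
    return inp.compressive_force * 1000.0 / inp.cross_section_area


@dataclass
class LayerSpec:
    """One layer of a tablet: a formulation compacted to a porosity.

    ``thickness_mm`` may be left ``None`` and derived from mass, porosity,
    true density and the punch cross-section:  t = m / ((1 - eps) rho A).
    """

    formulation: Formulation
    mass_mg: float
    porosity: float
    label: str
    thickness_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ValidationError(f"layer {self.label!r}: mass must be > 0")
        if not 0.0 <= self.porosity < 1.0:
            raise ValidationError(
                f"layer {self.label!r}: porosity must be in [0, 1)"
            )

    @property
    def true_density(self) -> float:
        return self.formulation.true_density

    def solid_volume_cm3(self) -> float:
        return (self.mass_mg / 1000.0) / self.true_density

    def envelope_volume_cm3(self) -> float:
        return self.solid_volume_cm3() / (1.0 - self.porosity)

    def derived_thickness_mm(self, cross_section_mm2: float) -> float:
        # volume mm^3 / area mm^2
        return self.envelope_volume_cm3() * 1000.0 / cross_section_mm2

    def resolved_thickness_mm(self, cross_section_mm2: float) -> float:
        """Stated thickness if given (validated to 1%), else derived."""
        derived = self.derived_thickness_mm(cross_section_mm2)
        if self.thickness_mm is None:
            return derived
        if abs(self.thickness_mm - derived) / derived > 0.01:
            raise InconsistentGeometryError(
                f"layer {self.label!r}: stated thickness {self.thickness_mm} mm "
                f"inconsistent with derived {derived:.4f} mm (> 1%)"
            )
        return self.thickness_mm


@dataclass
class TabletSpec:
    """Ordered bottom-to-top stack of layers on an oval punch footprint.

    ``shape_model`` selects how the "oval" outline is idealized: a true
    ellipse (default) or a stadium (rectangle capped by two half-discs).
    """

    layers: list[LayerSpec]
    punch_major_axis: float
    punch_minor_axis: float
    shape_model: str = "ellipse"
    name: str = "tablet"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("a tablet needs at least one layer")
        if self.punch_major_axis <= 0 or self.punch_minor_axis <= 0:
            raise ValidationError("punch axes must be > 0")
        if self.shape_model not in ("ellipse", "stadium"):
            raise ValidationError(
                f"unknown shape_model {self.shape_model!r}; "
                "expected 'ellipse' or 'stadium'"
            )

    @property
    def cross_section_mm2(self) -> float:
        return cross_section_area(self)

    @property
    def perimeter_mm(self) -> float:
        return perimeter(self)

    def layer_thicknesses_mm(self) -> list[float]:
        area = self.cross_section_mm2
        return [layer.resolved_thickness_mm(area) for layer in self.layers]

    @property
    def total_thickness_mm(self) -> float:
        return sum(self.layer_thicknesses_mm())

    @property
    def total_mass_mg(self) -> float:
        return sum(layer.mass_mg for layer in self.layers)


def cross_section_area(spec: TabletSpec) -> float:
    """Horizontal cross-section of the tablet, mm^2."""
    a, b = spec.punch_major_axis, spec.punch_minor_axis
    if spec.shape_model == "ellipse":
        return math.pi * (a / 2.0) * (b / 2.0)
    if spec.shape_model == "stadium":
        return (a - b) * b + math.pi * (b / 2.0) ** 2
    raise ValidationError(f"unknown shape_model {spec.shape_model!r}")


def perimeter(spec: TabletSpec) -> float:
    """Perimeter of the cross-section outline, mm.

    The ellipse perimeter uses the complete elliptic integral of the
    second kind (exact, not the Ramanujan approximation).
    """
    a, b = spec.punch_major_axis, spec.punch_minor_axis
    if spec.shape_model == "ellipse":
        semi_a, semi_b = a / 2.0, b / 2.0
        m = 1.0 - (semi_b / semi_a) ** 2
        return 4.0 * semi_a * float(ellipe(m))
    if spec.shape_model == "stadium":
        return 2.0 * (a - b) + math.pi * b
    raise ValidationError(f"unknown shape_model {spec.shape_model!r}")


def exposed_surface_area(spec: TabletSpec, layer_index: int) -> float:
    """Surface of one layer exposed to the dissolution medium, mm^2.

    A flat-faced prism model: the lateral band (perimeter x thickness)
    is always exposed; each end face contributes only when not occluded
    by an adjacent layer.  The middle layer of a triple-layer tablet
    therefore exposes its lateral band only.
    """
    n = len(spec.layers)
    if not 0 <= layer_index < n:
        raise ValidationError(f"layer_index {layer_index} out of range 0..{n - 1}")
    thickness = spec.layer_thicknesses_mm()[layer_index]
    area = perimeter(spec) * thickness
    face = cross_section_area(spec)
    if layer_index == 0:  # bottom face free
        area += face
    if layer_index == n - 1:  # top face free
        area += face
    return area


def surface_fraction_of_control(layer_area: float, control_area: float) -> int:
    """Layer surface as a whole-number percent of the standalone control."""
    if control_area <= 0:
        raise ValidationError("control_area must be > 0")
    return round(100.0 * layer_area / control_area)
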