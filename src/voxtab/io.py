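"""File formats: release-profile CSV, tablet/rule configs, reports.

The release-profile dialect is a UTF-8 CSV with header
``time_s,species,released_pct``, one row per (time, species), period as
decimal separator.  Lines starting with ``#`` are provenance comments
(package version, config hash, seed) and are ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ca import RuleSet, SimulationResult
from .errors import ValidationError
from .geometry import (
    Component,
    Formulation,
    LayerSpec,
    Role,
    SolubilityClass,
    TabletSpec,
)
from .kinetics import ReleaseProfile

__all__ = [
    "write_profiles",
    "read_profiles",
    "result_profiles",
    "tablet_spec_to_dict",
    "tablet_spec_from_dict",
    "rules_to_dict",
    "rules_from_dict",
    "load_config",
    "save_config",
    "config_hash",
    "provenance_header",
]

PROFILE_COLUMNS = ["time_s", "species", "released_pct"]


def config_hash(obj: Any) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: Any = None) -> str:
    lines = [f"# voxtab {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return "\n".join(lines) + "\n"


def write_profiles(
    path: str | Path,
    profiles: Iterable[ReleaseProfile],
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Write one or more release profiles to the CSV dialect."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {"time_s": p.times, "species": p.species, "released_pct": p.released}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        table.to_csv(fh, index=False, float_format="%.9g")


def read_profiles(path: str | Path) -> dict[str, ReleaseProfile]:
    """Read the CSV dialect back into per-species profiles."""
    table = pd.read_csv(path, comment="#")
    missing = set(PROFILE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"profile CSV {path} lacks columns {sorted(missing)}")
    out = {}
    for species, group in table.groupby("species", sort=True):
        group = group.sort_values("time_s")
        out[str(species)] = ReleaseProfile(
            times=group["time_s"].to_numpy(),
            released=group["released_pct"].to_numpy(),
            species=str(species),
        )
    return out


def result_profiles(result: SimulationResult) -> list[ReleaseProfile]:
    """Per-API release profiles of a simulation result."""
    return [
        ReleaseProfile(result.times, np.clip(curve, 0.0, 100.0), species=name)
        for name, curve in sorted(result.release_pct.items())
    ]


# --- tablet / rule configuration documents ------------------------------


def tablet_spec_to_dict(spec: TabletSpec) -> dict:
    return {
        "name": spec.name,
        "punch_major_axis_mm": spec.punch_major_axis,
        "punch_minor_axis_mm": spec.punch_minor_axis,
        "shape_model": spec.shape_model,
        "layers": [
            {
                "label": layer.label,
                "mass_mg": layer.mass_mg,
                "porosity": layer.porosity,
                "thickness_mm": layer.thickness_mm,
                "components": [
                    {
                        "name": c.name,
                        "weight_fraction": c.weight_fraction,
                        "true_density_g_cm3": c.true_density,
                        "solubility_class": c.solubility_class.value,
                        "dissolution_resistance": c.dissolution_resistance,
                        "role": c.role.value,
                    }
                    for c in layer.formulation
                ],
            }
            for layer in spec.layers
        ],
    }


def tablet_spec_from_dict(doc: dict) -> TabletSpec:
    try:
        layers = [
            LayerSpec(
                formulation=Formulation(
                    [
                        Component(
                            name=c["name"],
                            weight_fraction=c["weight_fraction"],
                            true_density=c["true_density_g_cm3"],
                            solubility_class=SolubilityClass(
                                c.get("solubility_class", "soluble")
                            ),
                            dissolution_resistance=c.get("dissolution_resistance", 1),
                            role=Role(c.get("role", "diluent")),
                        )
                        for c in rec["components"]
                    ]
                ),
                mass_mg=rec["mass_mg"],
                porosity=rec["porosity"],
                label=rec["label"],
                thickness_mm=rec.get("thickness_mm"),
            )
            for rec in doc["layers"]
        ]
        return TabletSpec(
            layers=layers,
            punch_major_axis=doc["punch_major_axis_mm"],
            punch_minor_axis=doc["punch_minor_axis_mm"],
            shape_model=doc.get("shape_model", "ellipse"),
            name=doc.get("name", "tablet"),
        )
    except KeyError as exc:
        raise ValidationError(f"tablet config is missing required field {exc}") from exc


def rules_to_dict(rules: RuleSet) -> dict:
    return {
        "ingress_probability": dict(rules.ingress_probability),
        "default_ingress": rules.default_ingress,
        "dissolution_resistance": (
            dict(rules.dissolution_resistance) if rules.dissolution_resistance else None
        ),
        "detachment_threshold": rules.detachment_threshold,
        "disintegrant_burst": rules.disintegrant_burst,
        "seconds_per_step": rules.seconds_per_step,
    }


def rules_from_dict(doc: dict) -> RuleSet:
    return RuleSet(
        ingress_probability=doc.get("ingress_probability", {}),
        default_ingress=doc.get("default_ingress", 1.0),
        dissolution_resistance=doc.get("dissolution_resistance"),
        detachment_threshold=doc.get("detachment_threshold", 0),
        disintegrant_burst=doc.get("disintegrant_burst", False),
        seconds_per_step=doc.get("seconds_per_step", 1.0),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration document."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(path: str | Path, doc: dict) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
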