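"""Run configuration: a flat, sectioned YAML file validated up front.

A run config selects the model source (generator parameters or mesh paths),
material properties, muscle specifications, gape-search settings, the
allometric scaling block and output options.  Unknown keys are rejected with
their location so typos fail before any stage runs.

Three demo profiles ship with the package, loosely themed on the three
study taxa: a large dirk-toothed machairodontine (259 kg), a sparassodont
saber-tooth (82 kg) and an extant conical-toothed leopard (68 kg).  Web
dimensions follow the published per-taxon values (ellipse 40x26 / 36x25 /
30x20 mm; circle radius 30 / 26 / 23 mm).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

_SCHEMA = {
    "name": str,
    "model": {
        "source": str,              # "generate" | "meshes"
        "skull_length_mm": float,
        "body_mass_kg": float,
        "canine_length_mm": (float, type(None)),
        "canine_arc_ratio": float,
        "bone_contact_gape_deg": float,
        "condyle_radius_mm": float,
        "cotyle_clearance_mm": float,
        "target_tets": int,
        "cranium_path": (str, type(None)),
        "mandible_path": (str, type(None)),
    },
    "materials": {
        "bone_e_mpa": float, "bone_nu": float,
        "dentine_e_mpa": float, "dentine_nu": float,
        "enamel_e_mpa": float, "enamel_nu": float,
    },
    "muscles": {
        "adductor_trusses_per_group": int,
        "specific_tension_mpa": float,
        "n_sternomastoideus": int,
        "n_obliquus_capitis": int,
        "pretension_n": float,
        "ellipse_axes_mm": list,
        "circle_radius_mm": float,
        "web_standoff_frac": float,
    },
    "gape": {
        "cartilage_mm": float,
        "backoff_deg": float,
        "contact_tol_mm": float,
        "angle_resolution_deg": float,
    },
    "scaling": {
        "exponent": float,
        "reference": str,
        "sweep_angles_deg": list,
    },
    "output": {"directory": str},
    "seed": int,
    "log_level": str,
}

DEFAULT_CONFIG = {
    "name": "synthetic",
    "model": {
        "source": "generate",
        "skull_length_mm": 300.0,
        "body_mass_kg": 259.0,
        "canine_length_mm": None,
        "canine_arc_ratio": 0.17,
        "bone_contact_gape_deg": 90.0,
        "condyle_radius_mm": 1.0,
        "cotyle_clearance_mm": 2.0,
        "target_tets": 5000,
        "cranium_path": None,
        "mandible_path": None,
    },
    "materials": {
        # literature-order defaults; the study's source values are unpublished
        "bone_e_mpa": 20000.0, "bone_nu": 0.3,
        "dentine_e_mpa": 21000.0, "dentine_nu": 0.31,
        "enamel_e_mpa": 80000.0, "enamel_nu": 0.3,
    },
    "muscles": {
        "adductor_trusses_per_group": 10,
        "specific_tension_mpa": 0.3,
        "n_sternomastoideus": 40,
        "n_obliquus_capitis": 30,
        "pretension_n": 25.0,
        "ellipse_axes_mm": [40.0, 26.0],
        "circle_radius_mm": 30.0,
        "web_standoff_frac": 0.5,
    },
    "gape": {
        "cartilage_mm": 1.0,
        "backoff_deg": 2.0,
        "contact_tol_mm": 0.05,
        "angle_resolution_deg": 0.01,
    },
    "scaling": {
        "exponent": 2.0 / 3.0,
        "reference": "dirktooth",
        "sweep_angles_deg": [15.0, 30.0, 45.0, 60.0, 75.0, 85.0],
    },
    "output": {"directory": "runs"},
    "seed": 0,
    "log_level": "INFO",
}

# demo profiles: overrides on top of DEFAULT_CONFIG
DEMO_PROFILES = {
    "dirktooth": {
        "name": "dirktooth",
        "model": {"skull_length_mm": 300.0, "body_mass_kg": 259.0,
                  "canine_arc_ratio": 0.17, "bone_contact_gape_deg": 90.0},
        "muscles": {"ellipse_axes_mm": [40.0, 26.0], "circle_radius_mm": 30.0},
    },
    "sparassodont": {
        "name": "sparassodont",
        "model": {"skull_length_mm": 250.0, "body_mass_kg": 82.0,
                  "canine_arc_ratio": 0.33, "bone_contact_gape_deg": 100.0},
        "muscles": {"ellipse_axes_mm": [36.0, 25.0], "circle_radius_mm": 26.0},
    },
    "leopard": {
        "name": "leopard",
        "model": {"skull_length_mm": 200.0, "body_mass_kg": 68.0,
                  "canine_arc_ratio": 0.45, "bone_contact_gape_deg": 75.0,
                  "canine_length_mm": 30.0},
        "muscles": {"ellipse_axes_mm": [30.0, 20.0], "circle_radius_mm": 23.0},
    },
}


class ConfigError(ValueError):
    pass


def _validate(data, schema, path="config"):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    for key, val in data.items():
        if key not in schema:
            raise ConfigError(f"{path}.{key}: unknown key")
        spec = schema[key]
        if isinstance(spec, dict):
            _validate(val, spec, f"{path}.{key}")
        else:
            types = spec if isinstance(spec, tuple) else (spec,)
            if float in types:
                types = types + (int,)
            if not isinstance(val, types):
                want = "/".join(t.__name__ for t in types)
                raise ConfigError(
                    f"{path}.{key}: expected {want}, got "
                    f"{type(val).__name__} ({val!r})")


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Validated run configuration (see DEFAULT_CONFIG for the full key set)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __post_init__(self):
        _validate(self.data, _SCHEMA)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @classmethod
    def from_profile(cls, profile: str, overrides: dict | None = None
                     ) -> "RunConfig":
        if profile not in DEMO_PROFILES:
            raise ConfigError(f"unknown demo profile '{profile}' "
                              f"(have {sorted(DEMO_PROFILES)})")
        data = _deep_merge(DEFAULT_CONFIG, DEMO_PROFILES[profile])
        if overrides:
            data = _deep_merge(data, overrides)
        return cls(data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as f:
            loaded = yaml.safe_load(f) or {}
        return cls(_deep_merge(DEFAULT_CONFIG, loaded))

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.data, f, sort_keys=False)

    # -- conversions ------------------------------------------------------
    def skull_params(self, seed: int | None = None):
        from sabrebite.synthetic import SkullParams

        m = self.data["model"]
        return SkullParams(
            skull_length=float(m["skull_length_mm"]),
            body_mass=float(m["body_mass_kg"]),
            canine_length=(None if m["canine_length_mm"] is None
                           else float(m["canine_length_mm"])),
            canine_arc_ratio=float(m["canine_arc_ratio"]),
            bone_contact_gape_deg=float(m["bone_contact_gape_deg"]),
            condyle_radius=float(m["condyle_radius_mm"]),
            cotyle_clearance=float(m["cotyle_clearance_mm"]),
            target_tets=int(m["target_tets"]),
            seed=self.seed if seed is None else seed,
            name=str(self.data["name"]),
        )

    def materials(self) -> dict:
        from sabrebite.fem import Material

        mt = self.data["materials"]
        return {
            0: Material("cortical_bone", mt["bone_e_mpa"], mt["bone_nu"]),
            1: Material("dentine", mt["dentine_e_mpa"], mt["dentine_nu"]),
            2: Material("enamel", mt["enamel_e_mpa"], mt["enamel_nu"]),
        }
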