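"""Versioned run-configuration schema: YAML in, SI out.

A single config file drives geometry, kinetics, transporter distribution,
protocol, solver tolerances, and output paths.  Physical quantities in the
file carry units ("50 mM", "100 um", "-0.3 MPa", "1 day"); bare numbers are
taken as SI.  Unknown keys and unknown units are rejected, and validation
reports every problem at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .geometry import RootGeometry, apply_barriers, build_root_grid, default_ring_spec, TissueRing
from .parameters import BoundaryConditions, ModelParams, TransporterDistribution
from .simulate import Protocol

SCHEMA_ID = "rootflux-config/1"

#: multiplicative factors to SI, keyed by unit string
UNIT_FACTORS = {
    # concentration -> mol m^-3
    "mM": 1.0, "mol/m^3": 1.0, "mol/m3": 1.0, "M": 1e3, "uM": 1e-3,
    # length -> m
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # time -> s
    "s": 1.0, "min": 60.0, "h": 3600.0, "day": 86400.0, "days": 86400.0,
    # pressure -> Pa
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6,
    # electrical -> V
    "V": 1.0, "mV": 1e-3,
    # transport coefficients (already SI)
    "m/s": 1.0, "m/s/Pa": 1.0, "m s^-1 Pa^-1": 1.0,
    "m^2/s": 1.0, "m2/s": 1.0,
    "m^2/Pa/s": 1.0, "m2/Pa/s": 1.0,
    "m^4/mol/s": 1.0, "m4/mol/s": 1.0, "m^4 mol^-1 s^-1": 1.0,
    "mol/m^2": 1.0, "mol/m2": 1.0,
    "F/m^2": 1.0, "F/m2": 1.0,
    "kg": 1.0, "g": 1e-3,
    "1": 1.0, "": 1.0,
}


class ConfigError(ValueError):
    """Validation failure; message lists every offending key path."""


def parse_quantity(value, key: str, errors: list) -> float:
    """'50 mM' -> 50.0; bare numbers pass through as SI."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split(None, 1)
        try:
            num = float(parts[0])
        except (ValueError, IndexError):
            errors.append(f"{key}: cannot parse quantity {value!r}")
            return float("nan")
        unit = parts[1].strip() if len(parts) > 1 else ""
        if unit not in UNIT_FACTORS:
            errors.append(f"{key}: unknown unit {unit!r} in {value!r}")
            return float("nan")
        return num * UNIT_FACTORS[unit]
    errors.append(f"{key}: expected number or 'number unit' string, got {type(value).__name__}")
    return float("nan")


_GEOM_KEYS = {
    "n_axial", "apex_layers", "cell_height", "apex_cell_height",
    "root_radius_scale",
    "apoplast_fraction", "cytosol_fraction", "vacuole_fraction",
    "plasmodesma_fraction", "tonoplast_area_ratio", "fresh_weight_override",
    "passage_cell_fraction",
}
_MEDIUM_KEYS = {"NaCl", "KCl", "Ca", "pH", "P_external", "P_shoot"}
_PROTOCOL_KEYS = {"pre_salt", "salt", "salt_onset", "duration", "output_times", "ramp"}
_DIST_KEYS = {"kind", "scenario", "k_ap"}
_SOLVER_KEYS = {"rtol", "atol"}
_OUTPUT_KEYS = {"dir", "formats"}
_TOP_KEYS = {"schema", "seed", "geometry", "kinetics", "distribution",
             "protocol", "solver", "output"}

#: ModelParams entries that are plain dicts (passed through unconverted)
_PARAM_DICT_FIELDS = {"D_free", "init_cytosol", "init_vacuole"}


@dataclass
class RunConfig:
    """A fully validated, SI-normalized run specification."""

    seed: int = 0
    geometry: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    distribution: dict = field(default_factory=lambda: {"kind": "wild_type"})
    protocol: dict = field(default_factory=dict)
    solver: dict = field(default_factory=lambda: {"rtol": 1e-6, "atol": 1e-9})
    output: dict = field(default_factory=lambda: {"dir": "out", "formats": ["csv"]})

    # -- builders ------------------------------------------------------------

    def build_geometry(self) -> RootGeometry:
        g = dict(self.geometry)
        g.pop("passage_cell_fraction", None)
        height = g.pop("cell_height", 1.0e-4)
        scale = g.pop("root_radius_scale", 1.0)
        rings = [
            TissueRing(r.name, r.radial_index, r.r_outer * scale,
                       r.r_inner * scale, height)
            for r in default_ring_spec(height)
        ]
        return build_root_grid(ring_spec=rings, **g)

    def build_graph(self, geometry: RootGeometry):
        return apply_barriers(
            geometry, self.geometry.get("passage_cell_fraction", 0.1)
        )

    def build_params(self) -> ModelParams:
        return ModelParams(**self.kinetics)

    def build_distribution(self, params: ModelParams) -> TransporterDistribution:
        kind = self.distribution.get("kind", "wild_type")
        if kind == "wild_type":
            return TransporterDistribution.wild_type(params)
        if kind == "sos1":
            return TransporterDistribution.sos1_mutant(params)
        if kind == "scenario":
            from .scenarios import enumerate_scenarios

            name = self.distribution["scenario"]
            match = [s for s in enumerate_scenarios() if s.name == name]
            if not match:
                raise ConfigError(f"distribution.scenario: unknown scenario {name!r}")
            spec = match[0].with_strength(self.distribution.get("k_ap", 1e-7))
            return spec.distribution(params)
        raise ConfigError(f"distribution.kind: unknown kind {kind!r}")

    def build_protocol(self) -> Protocol:
        p = dict(self.protocol)
        pre = BoundaryConditions(**p.get("pre_salt", {}))
        salt = BoundaryConditions(**p.get("salt", p.get("pre_salt", {})))
        return Protocol(
            pre_salt=pre,
            salt=salt,
            salt_onset=p.get("salt_onset", 0.0),
            duration=p.get("duration", 86400.0),
            output_times=p.get("output_times", []),
            ramp=p.get("ramp", 0.0),
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_ID,
            "seed": self.seed,
            "geometry": self.geometry,
            "kinetics": self.kinetics,
            "distribution": self.distribution,
            "protocol": self.protocol,
            "solver": self.solver,
            "output": self.output,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _check_keys(section: dict, allowed: set, prefix: str, errors: list):
    for k in section:
        if k not in allowed:
            errors.append(f"{prefix}.{k}: unknown key")


def _normalize_medium(d: dict, prefix: str, errors: list) -> dict:
    _check_keys(d, _MEDIUM_KEYS, prefix, errors)
    out = {}
    for k, v in d.items():
        if k == "pH":
            out[k] = float(v)
        else:
            out[k] = parse_quantity(v, f"{prefix}.{k}", errors)
    return out


def validate_config(raw: dict) -> RunConfig:
    """Validate and unit-normalize a raw mapping; raise ConfigError listing
    all problems at once."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config", errors)
    if raw.get("schema", SCHEMA_ID) != SCHEMA_ID:
        errors.append(f"schema: expected {SCHEMA_ID!r}, got {raw.get('schema')!r}")

    geom = dict(raw.get("geometry", {}))
    _check_keys(geom, _GEOM_KEYS, "geometry", errors)
    for k in ("cell_height", "apex_cell_height", "fresh_weight_override"):
        if k in geom and geom[k] is not None:
            geom[k] = parse_quantity(geom[k], f"geometry.{k}", errors)

    kin = dict(raw.get("kinetics", {}))
    valid_params = {f.name for f in dc_fields(ModelParams)}
    for k, v in list(kin.items()):
        if k not in valid_params:
            errors.append(f"kinetics.{k}: unknown parameter")
        elif k not in _PARAM_DICT_FIELDS:
            kin[k] = parse_quantity(v, f"kinetics.{k}", errors)

    dist = dict(raw.get("distribution", {"kind": "wild_type"}))
    _check_keys(dist, _DIST_KEYS, "distribution", errors)
    if "k_ap" in dist:
        dist["k_ap"] = parse_quantity(dist["k_ap"], "distribution.k_ap", errors)

    prot = dict(raw.get("protocol", {}))
    _check_keys(prot, _PROTOCOL_KEYS, "protocol", errors)
    for k in ("salt_onset", "duration", "ramp"):
        if k in prot:
            prot[k] = parse_quantity(prot[k], f"protocol.{k}", errors)
    if "output_times" in prot:
        prot["output_times"] = [
            parse_quantity(v, f"protocol.output_times[{i}]", errors)
            for i, v in enumerate(prot["output_times"])
        ]
    for med in ("pre_salt", "salt"):
        if med in prot:
            prot[med] = _normalize_medium(prot[med], f"protocol.{med}", errors)

    solver = dict(raw.get("solver", {}))
    _check_keys(solver, _SOLVER_KEYS, "solver", errors)
    output = dict(raw.get("output", {}))
    _check_keys(output, _OUTPUT_KEYS, "output", errors)

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        geometry=geom,
        kinetics=kin,
        distribution=dist,
        protocol=prot,
        solver={"rtol": float(solver.get("rtol", 1e-6)),
                "atol": float(solver.get("atol", 1e-9))},
        output=output or {"dir": "out", "formats": ["csv"]},
    )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)
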