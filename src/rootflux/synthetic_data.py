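"""Synthetic experimental-target generation.

Real optimization targets for this kind of model are literature measurements
(root Na+/K+ contents, xylem sap concentrations, epidermal transmembrane
potentials, Na+ flux to the shoot) collected under a handful of standard
hydroponic media.  This module emulates such a target table by forward
simulation at known "true" parameters plus configurable multiplicative
lognormal observational noise, so that the whole optimization pipeline is
testable without any external data.

The four bundled media presets reproduce commonly used experimental
conditions (mM; external pH):

========  =====  =====  ====  ===
name      NaCl   KCl    Ca    pH
========  =====  =====  ====  ===
essah     50     11.9   0.5   5.5
xylem     50     2.0    2.0   4.4
content   100    7.5    0.8   5.7
mife      50     0.5    0.1   5.5
========  =====  =====  ====  ===
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import RootModel
from .config import RunConfig
from .parameters import BoundaryConditions
from .simulate import (
    Protocol,
    Trajectory,
    epidermal_membrane_potential,
    flux_to_shoot_per_fw,
    root_ion_content_per_fw,
    run_protocol,
    solve_presalt_steady_state,
    xylem_sap_concentration,
)

logger = logging.getLogger(__name__)

MEDIA_PRESETS = {
    "essah": dict(NaCl=50.0, KCl=11.9, Ca=0.5, pH=5.5),
    "xylem": dict(NaCl=50.0, KCl=2.0, Ca=2.0, pH=4.4),
    "content": dict(NaCl=100.0, KCl=7.5, Ca=0.8, pH=5.7),
    "mife": dict(NaCl=50.0, KCl=0.5, Ca=0.1, pH=5.5),
}

#: observable name -> (extractor, units, optimization stage)
OBSERVABLES = {
    "root_Na_content": (lambda tr, t: root_ion_content_per_fw(tr, t, "Na"), "mol/kgFW", "outer"),
    "root_K_content": (lambda tr, t: root_ion_content_per_fw(tr, t, "K"), "mol/kgFW", "outer"),
    "epidermal_potential": (
        lambda tr, t: epidermal_membrane_potential(tr, t, tr.model.geometry.n_axial - 1),
        "V", "outer"),
    "xylem_Na": (lambda tr, t: xylem_sap_concentration(tr, t, "Na"), "mol/m3", "stele"),
    "xylem_K": (lambda tr, t: xylem_sap_concentration(tr, t, "K"), "mol/m3", "stele"),
    "xylem_Cl": (lambda tr, t: xylem_sap_concentration(tr, t, "Cl"), "mol/m3", "stele"),
    "Na_flux_to_shoot": (lambda tr, t: flux_to_shoot_per_fw(tr, t, "Na"), "mol/s/kgFW", "stele"),
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal observational noise.

    ``sd`` is the standard deviation of log-observations (a relative noise
    scale, appropriate for positive quantities spanning decades);
    per-observable overrides via ``per_observable``.
    """

    sd: float = 0.0
    seed: int = 0
    per_observable: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sd < 0 or any(v < 0 for v in self.per_observable.values()):
            raise ValueError("noise sd must be >= 0")

    def sd_for(self, observable: str) -> float:
        return self.per_observable.get(observable, self.sd)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: medium x genotype x observation time."""

    medium: str  # key of MEDIA_PRESETS
    genotype: str = "wild_type"
    time: float = 86400.0  # s after salt onset
    observables: tuple = tuple(OBSERVABLES)

    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(**MEDIA_PRESETS[self.medium])


def default_conditions() -> list[Condition]:
    """Wild-type and sos1 mutant, content and flux media, day 1."""
    return [
        Condition("essah", "wild_type"),
        Condition("essah", "sos1"),
        Condition("content", "wild_type",
                  observables=("root_Na_content", "root_K_content", "epidermal_potential")),
        Condition("xylem", "wild_type",
                  observables=("xylem_Na", "xylem_K", "xylem_Cl")),
    ]


def make_truth_config(preset: str = "toy") -> RunConfig:
    """Full model configuration with the calibrated 'true' parameters.

    ``toy`` is a 6-layer root (2 apex layers) that reaches its pre-salt
    steady state in seconds; ``default`` is the 30-layer root (5 apex
    layers) used for the headline simulations.
    """
    if preset == "toy":
        geometry = {"n_axial": 6, "apex_layers": 2}
    elif preset == "default":
        geometry = {"n_axial": 30, "apex_layers": 5}
    else:
        raise ValueError(f"unknown preset {preset!r} (expected 'toy' or 'default')")
    return RunConfig(
        geometry=geometry,
        kinetics={},  # ModelParams defaults are the truth values
        distribution={"kind": "wild_type"},
        protocol={
            "pre_salt": dict(NaCl=0.5, KCl=11.9, Ca=0.5, pH=5.5),
            "salt": dict(NaCl=50.0, KCl=11.9, Ca=0.5, pH=5.5),
            "salt_onset": 0.0,
            "duration": 86400.0,
            "output_times": [0.0, 86400.0],
        },
    )


def simulate_condition(
    config: RunConfig, condition: Condition, rtol=1e-6, atol=1e-9
) -> Trajectory:
    """Forward-simulate one condition from its own pre-salt steady state."""
    geometry = config.build_geometry()
    graph = config.build_graph(geometry)
    params = config.build_params()
    if condition.genotype == "sos1":
        from .parameters import TransporterDistribution

        dist = TransporterDistribution.sos1_mutant(params)
    else:
        dist = config.build_distribution(params)
    salt_bc = condition.boundary_conditions()
    pre_bc = BoundaryConditions(
        NaCl=min(0.5, salt_bc.NaCl), KCl=salt_bc.KCl, Ca=salt_bc.Ca, pH=salt_bc.pH
    )
    model = RootModel(geometry, graph, params, dist, pre_bc)
    y0 = solve_presalt_steady_state(model, pre_bc, rtol=rtol, atol=atol)
    protocol = Protocol(
        pre_salt=pre_bc, salt=salt_bc, salt_onset=0.0,
        duration=condition.time, output_times=[0.0, condition.time],
    )
    return run_protocol(model, y0, protocol, rtol=rtol, atol=atol)


def generate_targets(
    config: RunConfig,
    conditions: list[Condition] | None = None,
    noise: NoiseModel = NoiseModel(),
    rtol=1e-6,
    atol=1e-9,
) -> pd.DataFrame:
    """Forward-simulate each condition and emit a noisy target table.

    Rows follow the target-table schema used by the optimizer: observable,
    genotype, medium composition, time, value, units, weight, stage.  With
    ``noise.sd == 0`` the table equals the forward-model observables exactly.
    A condition whose simulation fails is omitted with a logged reason.
    """
    conditions = conditions if conditions is not None else default_conditions()
    rng = np.random.default_rng(noise.seed)
    rows = []
    cache: dict[tuple, Trajectory] = {}  # one simulation per distinct condition
    for cond in conditions:
        key = (cond.medium, cond.genotype, cond.time)
        try:
            if key not in cache:
                cache[key] = simulate_condition(config, cond, rtol=rtol, atol=atol)
            traj = cache[key]
        except Exception as exc:
            logger.warning("condition %s/%s failed: %s", cond.medium, cond.genotype, exc)
            continue
        med = MEDIA_PRESETS[cond.medium]
        for name in cond.observables:
            fn, units, stage = OBSERVABLES[name]
            value = fn(traj, cond.time)
            sd = noise.sd_for(name)
            if sd > 0:
                # multiplicative lognormal noise preserves the sign
                value = value * float(np.exp(rng.normal(0.0, sd)))
            rows.append({
                "observable": name,
                "genotype": cond.genotype,
                "medium": cond.medium,
                "NaCl": med["NaCl"], "KCl": med["KCl"],
                "Ca": med["Ca"], "pH": med["pH"],
                "time_s": cond.time,
                "value": value,
                "units": units,
                "weight": 1.0,
                "stage": stage,
            })
    return pd.DataFrame(rows)


def recovery_experiment(
    truth_config: RunConfig,
    noise: NoiseModel,
    optimizer_config: dict | None = None,
) -> dict:
    """Generate targets at known truth, fit, and report parameter recovery."""
    from .optimize import two_stage_fit

    targets = generate_targets(truth_config, noise=noise)
    opt = dict(optimizer_config or {})
    outer_fit, stele_fit = two_stage_fit(truth_config, targets, **opt)
    report = {"targets": targets, "outer": outer_fit, "stele": stele_fit,
              "recovery": {}}
    truth = truth_config.build_params()
    for fit in (outer_fit, stele_fit):
        for name, value in fit.parameters.items():
            true_val = _lookup_truth(truth, name)
            rel = abs(value - true_val) / abs(true_val) if true_val else np.inf
            report["recovery"][name] = {
                "true": true_val, "fitted": value, "rel_error": rel,
                "identifiable": fit.identifiable.get(name, True),
            }
    return report


def _lookup_truth(params, name: str) -> float:
    return getattr(params, name)
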