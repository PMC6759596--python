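"""SOS1 spatial-distribution scenarios: enumeration, sweeps, classification.

The plasma-membrane Na+/H+ antiporter (SOS1) is placed in specific tissue
regions and developmental zones; all other parameters stay fixed.  The six
scenario groups (17 spatial patterns in total):

* individual mature tissues (epidermis, cortex, endodermis, xylem parenchyma);
* individual apex tissues (the four above plus the non-functional xylem);
* mature-zone combinations (epidermis+xylem parenchyma, cortex+xylem
  parenchyma, all outer tissues, all mature tissues);
* mature-and-apex combinations (apical epidermis + mature xylem parenchyma,
  all apex tissues + mature xylem parenchyma);
* all apex tissues;
* all root tissues.

Mature-zone patterns carry no apex antiporters and vice versa.  Each pattern
is swept over antiporter strengths {1, 10, 100, 1000} x 1e-8 m^4 mol^-1 s^-1.
A scenario outcome is "reasonable" when both the root Na+ content and the
Na+ flux to the shoot lie within 50% (inclusive) of the wild-type reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import RootGeometry, ConnectivityGraph
from .parameters import (
    APEX_TISSUES,
    LIVING_TISSUES,
    OUTER_TISSUES,
    BoundaryConditions,
    ModelParams,
    TransporterDistribution,
)
from .assembly import RootModel
from .simulate import (
    Protocol,
    antiporter_xylem_loading,
    flux_to_shoot_per_fw,
    mean_cytosolic_concentration,
    root_ion_content_per_fw,
    run_protocol,
    solve_presalt_steady_state,
    water_flux_to_shoot,
)

#: canonical strength grid, m^4 mol^-1 s^-1
STRENGTH_GRID = (1e-8, 1e-7, 1e-6, 1e-5)


@dataclass(frozen=True)
class ScenarioSpec:
    """One antiporter placement pattern plus its run conditions."""

    name: str
    antiporter_map: frozenset  # of (zone, tissue) pairs
    k_ap: float = 1e-7
    genotype: str = "wild_type"  # or "sos1"

    def __post_init__(self):
        valid = {("mature", t) for t in LIVING_TISSUES} | {
            ("apex", t) for t in APEX_TISSUES
        }
        bad = set(self.antiporter_map) - valid
        if bad:
            raise ValueError(f"invalid antiporter locations: {sorted(bad)}")
        if self.k_ap < 0:
            raise ValueError("k_ap must be >= 0")
        if self.genotype not in ("wild_type", "sos1"):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    def distribution(self, params: ModelParams) -> TransporterDistribution:
        base = TransporterDistribution.wild_type(params)
        k = self.k_ap
        if self.genotype == "sos1":
            k = k * params.sos1_residual_fraction
        return TransporterDistribution(
            antiporter_k_ap={loc: k for loc in self.antiporter_map},
            hkt_locations=base.hkt_locations,
            tono_nhx_zones=base.tono_nhx_zones,
        )

    def with_strength(self, k_ap: float) -> "ScenarioSpec":
        return replace(self, k_ap=k_ap)


def _pat(name: str, mature=(), apex=()) -> ScenarioSpec:
    locs = frozenset(
        {("mature", t) for t in mature} | {("apex", t) for t in apex}
    )
    return ScenarioSpec(name=name, antiporter_map=locs)


def enumerate_scenarios() -> list[ScenarioSpec]:
    """The 17 spatial patterns of the six scenario groups (strengths unset)."""
    pats = []
    # group 1: individual mature tissues
    for t in LIVING_TISSUES:
        pats.append(_pat(f"mature_{t}", mature=[t]))
    # group 2: individual apex tissues ("xylem" is the non-functional xylem)
    for t in APEX_TISSUES:
        label = "non_functional_xylem" if t == "xylem" else t
        pats.append(_pat(f"apex_{label}", apex=[t]))
    # group 3: mature combinations
    pats.append(_pat("mature_epidermis_xylem_parenchyma",
                     mature=["epidermis", "xylem_parenchyma"]))
    pats.append(_pat("mature_cortex_xylem_parenchyma",
                     mature=["cortex", "xylem_parenchyma"]))
    pats.append(_pat("mature_outer", mature=list(OUTER_TISSUES)))
    pats.append(_pat("mature_all", mature=list(LIVING_TISSUES)))
    # group 4: mature-and-apex combinations
    pats.append(_pat("apex_epidermis_mature_xylem_parenchyma",
                     mature=["xylem_parenchyma"], apex=["epidermis"]))
    pats.append(_pat("apex_all_mature_xylem_parenchyma",
                     mature=["xylem_parenchyma"], apex=list(APEX_TISSUES)))
    # group 5: all apex tissues
    pats.append(_pat("apex_all", apex=list(APEX_TISSUES)))
    # group 6: all root tissues
    pats.append(_pat("all_tissues", mature=list(LIVING_TISSUES),
                     apex=list(APEX_TISSUES)))
    assert len(pats) == 17
    return pats


def strength_grid() -> list[float]:
    """Antiporter strengths swept per pattern (ascending)."""
    return list(STRENGTH_GRID)


@dataclass
class SweepConfig:
    geometry: RootGeometry
    graph: ConnectivityGraph
    params: ModelParams
    protocol: Protocol
    observation_time: float  # s since protocol start
    rtol: float = 1e-6
    atol: float = 1e-9


def run_scenario(spec: ScenarioSpec, cfg: SweepConfig) -> dict:
    """Run one scenario end to end and extract the sweep observables."""
    dist = spec.distribution(cfg.params)
    model = RootModel(cfg.geometry, cfg.graph, cfg.params, dist,
                      cfg.protocol.pre_salt)
    y0 = solve_presalt_steady_state(model, cfg.protocol.pre_salt,
                                    rtol=cfg.rtol, atol=cfg.atol)
    traj = run_protocol(model, y0, cfg.protocol, rtol=cfg.rtol, atol=cfg.atol)
    t = cfg.observation_time
    row = {
        "scenario": spec.name,
        "k_ap": spec.k_ap,
        "genotype": spec.genotype,
        "time_s": t,
        "root_Na_content_mol_per_kg": root_ion_content_per_fw(traj, t, "Na"),
        "Na_flux_to_shoot_mol_per_s_kg": flux_to_shoot_per_fw(traj, t, "Na"),
        "water_flux_to_shoot_m3_per_s": water_flux_to_shoot(traj, t),
        "mean_cyt_Na_mature_mol_m3": mean_cytosolic_concentration(traj, t, "mature", "Na"),
        "mean_cyt_Na_apex_mol_m3": mean_cytosolic_concentration(traj, t, "apex", "Na"),
        "antiporter_xylem_loading_mol_per_s": antiporter_xylem_loading(traj, t),
        "status": "ok",
        "error": "",
    }
    return row


def run_sweep(
    patterns: list[ScenarioSpec],
    strengths: list[float],
    cfg: SweepConfig,
) -> pd.DataFrame:
    """One row per (pattern, strength); failures are flagged per row rather
    than aborting the sweep.  Row order is deterministic."""
    rows = []
    for pat in patterns:
        for k in strengths:
            spec = pat.with_strength(k)
            try:
                rows.append(run_scenario(spec, cfg))
            except Exception as exc:  # failure diagnostics stay in the table
                rows.append({
                    "scenario": pat.name, "k_ap": k, "genotype": pat.genotype,
                    "time_s": cfg.observation_time,
                    "root_Na_content_mol_per_kg": np.nan,
                    "Na_flux_to_shoot_mol_per_s_kg": np.nan,
                    "water_flux_to_shoot_m3_per_s": np.nan,
                    "mean_cyt_Na_mature_mol_m3": np.nan,
                    "mean_cyt_Na_apex_mol_m3": np.nan,
                    "antiporter_xylem_loading_mol_per_s": np.nan,
                    "status": "failed",
                    "error": f"{type(exc).__name__}: {exc}",
                })
    return pd.DataFrame(rows)


def classify_reasonable(row, wt_reference: dict) -> bool:
    """True when both the Na+ root content and the Na+ flux to shoot lie
    within 50% (inclusive) of the wild-type reference values."""
    ref_c = wt_reference["content"]
    ref_f = wt_reference["flux"]
    if ref_c <= 0 or ref_f <= 0:
        raise ValueError("wild-type reference content and flux must be > 0")
    content = row["root_Na_content_mol_per_kg"] if hasattr(row, "__getitem__") else row.content
    flux = row["Na_flux_to_shoot_mol_per_s_kg"]
    # inclusive boundary, robust to roundoff at exactly 50%
    tol = 0.5 * (1.0 + 1e-9)
    return (
        abs(content - ref_c) / ref_c <= tol
        and abs(flux - ref_f) / ref_f <= tol
    )
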