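"""Model parameter containers and Arabidopsis-plausible defaults.

The transporter complement follows the standard picture of the Arabidopsis
root: plasma-membrane H+-ATPases energize every living cell; K+ moves through
inward (AKT1-like) and outward (GORK/SKOR-like) rectifiers and a K+/H+
symporter; Cl- enters through a Cl-/2H+ symporter and leaves through an anion
channel; Na+ enters passively through Ca-blockable nonselective cation
channels (NSCC), is retrieved from the stelar apoplast by HKT1;1, and is
actively effluxed by plasma-membrane Na+/H+ antiporters (SOS1) whose spatial
distribution is the object of the scenario analysis.  Tonoplasts carry a
V-type H+ pump, NHX-type Na+/H+ (mature zone only) and K+/H+ antiporters, and
leak channels.

Default antiporter strengths are 2e-7 (outer tissues) and 3e-7 (stele)
m^4 mol^-1 s^-1; the remaining kinetic constants are this package's own
calibrated defaults (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import GAS_CONSTANT, TEMPERATURE
from .kinetics import CarrierCycleParams

ZONES = ("apex", "mature")
LIVING_TISSUES = ("epidermis", "cortex", "endodermis", "xylem_parenchyma")
#: the apex xylem ("non-functional xylem") is a living cell and may carry
#: transporters; in the mature zone the xylem is an apoplastic conduit.
APEX_TISSUES = LIVING_TISSUES + ("xylem",)
OUTER_TISSUES = ("epidermis", "cortex", "endodermis")


def ph_to_conc(pH: float) -> float:
    """pH -> free H+ concentration in mol m^-3."""
    return 1000.0 * 10.0 ** (-pH)


@dataclass(frozen=True)
class BoundaryConditions:
    """External medium composition and the hydraulic boundary pressures."""

    NaCl: float = 0.0  # mol m^-3
    KCl: float = 1.0
    Ca: float = 0.5
    pH: float = 5.7
    P_external: float = 0.0  # Pa, gauge
    P_shoot: float = -0.3e6  # Pa at the top of the xylem conduit

    def __post_init__(self):
        if not (2.0 < self.pH < 9.0):
            raise ValueError(f"external pH must be in (2, 9), got {self.pH}")
        for name in ("NaCl", "KCl", "Ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def conc(self) -> dict[str, float]:
        """External free-solution concentrations; Ca enters as CaCl2."""
        return {
            "Na": self.NaCl,
            "K": self.KCl,
            "Cl": self.NaCl + self.KCl + 2.0 * self.Ca,
            "H": ph_to_conc(self.pH),
        }

    def osmotic_pressure(self, T: float = TEMPERATURE) -> float:
        c = self.conc
        total = c["Na"] + c["K"] + c["Cl"] + c["H"] + self.Ca
        return GAS_CONSTANT * T * total

    def with_salt(self, NaCl: float) -> "BoundaryConditions":
        return replace(self, NaCl=NaCl)


# ---------------------------------------------------------------------------
# carrier-cycle templates


def pm_proton_pump(density: float = 4.0e-8) -> CarrierCycleParams:
    """Plasma-membrane H+-ATPase: exports one H+ per cycle (z_t = +1).

    The strong forward bias of the rate products encodes the ATP free energy;
    defaults give a resting potential near -120 mV and an apoplastic pH near
    5.5 in the calibrated root.
    """
    return CarrierCycleParams(
        rates={
            "k12": 5.0e5,  # m^3 mol^-1 s^-1, binds cytosolic H+ (limits the
            # cycle near pH 7, so pumping self-regulates cytosolic pH)
            "k21": 1.0e3,
            "k23": 8.0e2,  # translocation, voltage dependent
            "k32": 2.5e1,
            "k34": 1.0e4,  # release to apoplast
            "k43": 2.5e2,  # m^3 mol^-1 s^-1, binds apoplastic H+
            "k41": 5.0e2,  # empty carrier return
            "k14": 5.0,
        },
        # cycle bias k12 k23 k34 k41 / (k21 k32 k43 k14) ~ 6e7 ~ exp(-dG_ATP/RT)
        N=density,
        z_t=1.0,
        binding={"k12": [("H", "in")], "k43": [("H", "out")]},
        cargo={"H": 1.0},
    )


def tonoplast_proton_pump(density: float = 2.0e-8) -> CarrierCycleParams:
    """V-type tonoplast H+ pump ('out' side = vacuole lumen)."""
    return CarrierCycleParams(
        rates={
            "k12": 5.0e5,
            "k21": 1.0e3,
            "k23": 4.0e2,
            "k32": 6.2e1,
            "k34": 1.0e4,
            "k43": 2.0e3,
            "k41": 5.0e2,
            "k14": 1.0e3,
        },
        # weaker bias (~8e3 per H+) than the plasma-membrane pump: the
        # V-ATPase moves ~2 H+ per ATP, so the per-H+ driving force is halved
        N=density,
        z_t=1.0,
        binding={"k12": [("H", "in")], "k43": [("H", "out")]},
        cargo={"H": 1.0},
    )


def kh_symporter(density: float = 3.0e-10) -> CarrierCycleParams:
    """K+/H+ symporter (HAK5-like), 1:1, passive secondary-active.

    The cycle is written in the efflux direction; under physiological
    gradients (apoplastic H+ excess) it runs in reverse, importing K+.
    """
    return CarrierCycleParams(
        # symmetric rates: detailed balance holds exactly (no phantom
        # energy input for a passive secondary-active carrier)
        rates={
            "k12": 1.0e7,  # binds K_in * H_in (m^6 mol^-2 s^-1)
            "k21": 1.0e4,
            "k23": 1.0e3,
            "k32": 1.0e3,
            "k34": 1.0e4,
            "k43": 1.0e7,  # binds K_out * H_out
            "k41": 1.0e3,
            "k14": 1.0e3,
        },
        N=density,
        z_t=2.0,
        binding={"k12": [("K", "in"), ("H", "in")], "k43": [("K", "out"), ("H", "out")]},
        cargo={"K": 1.0, "H": 1.0},
    )


def clh_symporter(density: float = 2.0e-11) -> CarrierCycleParams:
    """Cl-/2H+ symporter; reverse operation imports Cl- driven by the pH
    gradient (net charge +1 outward per forward cycle)."""
    return CarrierCycleParams(
        # symmetric rates: detailed balance (passive carrier)
        rates={
            "k12": 1.0e8,  # binds Cl_in * H_in^2 (m^9 mol^-3 s^-1)
            "k21": 1.0e4,
            "k23": 1.0e3,
            "k32": 1.0e3,
            "k34": 1.0e4,
            "k43": 1.0e8,  # binds Cl_out * H_out^2
            "k41": 1.0e3,
            "k14": 1.0e3,
        },
        N=density,
        z_t=1.0,
        binding={
            "k12": [("Cl", "in"), ("H", "in"), ("H", "in")],
            "k43": [("Cl", "out"), ("H", "out"), ("H", "out")],
        },
        cargo={"Cl": 1.0, "H": 2.0},
    )


# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Every kinetic, hydraulic and numerical parameter of the root model.

    Permeabilities in m s^-1, hydraulic conductivities Lp in m s^-1 Pa^-1,
    wall hydraulic coefficients k_h in m^2 Pa^-1 s^-1, mass-action antiporter
    coefficients in m^4 mol^-1 s^-1, concentrations in mol m^-3.
    """

    T: float = TEMPERATURE

    # --- electro-regularization (see docs/methods.md): each compartment
    # carries c_membrane F m^-2 of capacitance per unit incident membrane
    # area; potentials are then explicit functions of the accumulated net
    # charge and electroneutrality holds to `electroneutrality_tolerance`.
    c_membrane: float = 5.0e-2

    # --- walls and pressure
    eps_cell: float = 5.0e6  # Pa, volumetric elastic modulus of living cells
    eps_apoplast: float = 5.0e7  # Pa, near-rigid wall space

    # --- water
    Lp_pm: float = 1.0e-13
    sigma_pm: float = 0.95
    Lp_tonoplast: float = 1.0e-12
    sigma_tonoplast: float = 1.0
    Lp_pd: float = 1.0e-9  # plasmodesmata, per unit pore area
    sigma_pd: float = 0.0
    k_h_wall: float = 5.0e-16
    k_h_xylem: float = 2.0e-11  # open conduit

    # --- free-solution diffusivities (m^2 s^-1)
    D_free: dict = field(
        default_factory=lambda: {"Na": 1.33e-9, "K": 1.96e-9, "Cl": 2.03e-9, "H": 9.3e-9}
    )
    tortuosity_wall: float = 0.3
    tortuosity_symplast: float = 0.5
    tortuosity_xylem: float = 1.0

    # --- fixed charge and proton buffers
    apoplast_fixed_charge: float = 2.0  # mol m^-3 negative equivalents
    conduit_fixed_charge: float = 0.0
    K_b_cytosol: float = 1.0e-4  # mol m^-3 (pK ~ 7)
    K_b_vacuole: float = 3.16e-3  # mol m^-3 (pK ~ 5.5)
    pH_cytosol_init: float = 7.2
    pH_vacuole_init: float = 5.5
    init_cytosol: dict = field(default_factory=lambda: {"Na": 5.0, "K": 100.0, "Cl": 15.0})
    init_vacuole: dict = field(default_factory=lambda: {"Na": 10.0, "K": 80.0, "Cl": 20.0})

    # --- plasma-membrane channels
    P_nscc: float = 8.0e-10  # Na and K, before Ca block
    #: the apex carries a different channel complement from the mature zone;
    #: its nonselective cation conductance is scaled by this factor
    nscc_apex_scale: float = 1.0
    K_Ca: float = 0.3  # mol m^-3 half-block constant
    P_kir: float = 1.0e-8
    kir_V_half: float = -0.10  # V
    kir_slope: float = 0.02
    P_kor: float = 2.0e-8
    kor_offset: float = 0.0  # V relative to E_K(apoplast)
    kor_slope: float = 0.02
    K_cytosol_ref: float = 100.0
    P_hkt: float = 2.0e-8  # Na-selective, mature stele
    P_anion_pm: float = 5.0e-10  # Cl
    P_h_pm: float = 5.0e-7

    # --- tonoplast channels
    P_tono_na: float = 2.0e-9
    P_tono_k: float = 5.0e-9
    P_tono_cl: float = 1.0e-9
    P_tono_h: float = 1.0e-8

    # --- pumps and symporters (carrier cycles)
    pm_pump_density: float = 4.0e-8
    #: stelar membranes (xylem parenchyma, apex xylem) carry proportionally
    #: more H+-ATPase: the stelar apoplast has no contact with the buffered
    #: medium, so xylem loading is limited by the locally pumped H+
    pump_density_stele_scale: float = 2.0
    tono_pump_density: float = 2.0e-8
    kh_symporter_density: float = 3.0e-10
    clh_symporter_density: float = 2.0e-11

    # --- antiporters (mass action)
    k_ap_outer: float = 2.0e-7  # PM Na+/H+, outer tissues
    k_ap_stele: float = 3.0e-7  # PM Na+/H+, stele
    k_ap_tono_na: float = 2.0e-8  # NHX-type, mature zone only
    k_ap_tono_k: float = 1.0e-8
    sos1_residual_fraction: float = 0.1

    def pm_pump(self) -> CarrierCycleParams:
        return pm_proton_pump(self.pm_pump_density)

    def tono_pump(self) -> CarrierCycleParams:
        return tonoplast_proton_pump(self.tono_pump_density)

    def kh_symporter_params(self) -> CarrierCycleParams:
        return kh_symporter(self.kh_symporter_density)

    def clh_symporter_params(self) -> CarrierCycleParams:
        return clh_symporter(self.clh_symporter_density)


# ---------------------------------------------------------------------------


@dataclass
class TransporterDistribution:
    """Spatial placement of the variable transporter families.

    ``antiporter_k_ap`` maps (zone, tissue) -> plasma-membrane Na+/H+
    antiporter strength (m^4 mol^-1 s^-1); absent keys mean no antiporter on
    that membrane.  Channels, pumps and symporters are present on every
    living plasma membrane; HKT1;1 and the tonoplast NHX antiporter follow
    their own location sets.
    """

    antiporter_k_ap: dict[tuple[str, str], float] = field(default_factory=dict)
    hkt_locations: frozenset = frozenset({("mature", "xylem_parenchyma")})
    tono_nhx_zones: frozenset = frozenset({"mature"})

    @classmethod
    def wild_type(cls, params: ModelParams) -> "TransporterDistribution":
        """Antiporters in all living tissues: outer strength in the outer
        tissues, stele strength in the xylem parenchyma and apex xylem."""
        amap: dict[tuple[str, str], float] = {}
        for zone in ZONES:
            tissues = APEX_TISSUES if zone == "apex" else LIVING_TISSUES
            for t in tissues:
                if t in OUTER_TISSUES:
                    amap[(zone, t)] = params.k_ap_outer
                else:
                    amap[(zone, t)] = params.k_ap_stele
        return cls(antiporter_k_ap=amap)

    @classmethod
    def sos1_mutant(cls, params: ModelParams) -> "TransporterDistribution":
        """Residual (low, nonzero) antiporter activity everywhere."""
        wt = cls.wild_type(params)
        f = params.sos1_residual_fraction
        return cls(
            antiporter_k_ap={k: f * v for k, v in wt.antiporter_k_ap.items()},
            hkt_locations=wt.hkt_locations,
            tono_nhx_zones=wt.tono_nhx_zones,
        )

    def k_ap_for(self, zone: str, tissue: str) -> float:
        return self.antiporter_k_ap.get((zone, tissue), 0.0)
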