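"""Closed-form membrane flux laws.

Sign convention everywhere: membrane potential ``V`` is inside minus outside,
and a positive molar flux leaves the inner compartment (efflux from the
cytosol to the apoplast, vacuole, or external medium).  All functions are
``numpy``-vectorized: scalars or equal-shaped arrays may be passed.

Families covered:

* Goldman-Hodgkin-Katz (constant-field) channel flux, with optional
  two-state Boltzmann voltage gating (KIR/KOR), an apoplastic-K-dependent
  gating midpoint for outward rectifiers, and hyperbolic external-Ca block of
  nonselective cation channels.
* 1:1 Na+/H+ mass-action antiporters (SOS1 on the plasma membrane, NHX-type
  on the tonoplast), electroneutral by stoichiometry.
* Four-state carrier cycles (King-Altman steady state) for the H+ pumps and
  the K+/H+ and Cl-/2H+ symporters, with symmetric Eyring voltage factors on
  the charge-translocating step.
* Nonequilibrium-thermodynamic water fluxes: hydraulic + osmotic across
  plasma membranes and plasmodesmata, osmotic-only across the tonoplast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import FARADAY, GAS_CONSTANT, TEMPERATURE


class KineticsValidationError(ValueError):
    pass


def osmotic_pressure(total_concentration, T: float = TEMPERATURE):
    """Ideal van 't Hoff osmotic pressure, pi = RT * sum(c) (Pa)."""
    return GAS_CONSTANT * T * np.asarray(total_concentration, dtype=float)


# ---------------------------------------------------------------------------
# channels


def ghk_flux(P, z, V, c_in, c_out, T: float = TEMPERATURE):
    """GHK constant-field molar flux (mol m^-2 s^-1, positive = efflux).

    J = P * u * (c_in - c_out * exp(-u)) / (1 - exp(-u)),  u = zFV/RT,
    with the analytic limit J -> P * (c_in - c_out) as V -> 0.
    """
    u = np.asarray(z * FARADAY * np.asarray(V, dtype=float) / (GAS_CONSTANT * T))
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    small = np.abs(u) < 1e-7
    large = np.abs(u) > 50.0  # exp saturated: J -> P u c_in (u>0), P u c_out (u<0)
    us = np.where(small | large, 1.0, u)  # avoid 0/0 and overflow; replaced below
    em = np.expm1(-us)
    exact = P * us * (c_in - c_out * (em + 1.0)) / (-em)
    series = P * ((c_in - c_out) + 0.5 * u * (c_in + c_out))
    asym = P * u * np.where(u > 0, c_in, c_out)
    return np.where(small, series, np.where(large, asym, exact))


def boltzmann_open_probability(V, V_half, slope, polarity: str):
    """Two-state Boltzmann open probability.

    ``polarity='inward'`` channels open on hyperpolarization (p -> 1 as
    V -> -inf); ``'outward'`` open on depolarization; ``'none'`` returns 1.
    """
    if polarity == "none":
        return np.ones_like(np.asarray(V, dtype=float))
    if np.any(np.asarray(slope) == 0):
        raise KineticsValidationError("gating slope must be nonzero")
    x = (np.asarray(V, dtype=float) - V_half) / slope
    if polarity == "inward":
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))
    if polarity == "outward":
        return 1.0 / (1.0 + np.exp(np.clip(-x, -500, 500)))
    raise KineticsValidationError(f"unknown polarity {polarity!r}")


def kor_gating_midpoint(K_apoplast, K_cytosol_ref, offset: float = 0.0,
                        T: float = TEMPERATURE):
    """Gating midpoint of outward-rectifying K+ channels.

    The midpoint tracks the K+ Nernst potential of the local apoplast,
    V_half = E_K + offset with E_K = (RT/F) ln(K_apo / K_cyt_ref), so the
    channel stays an efflux pathway as apoplastic K+ varies.
    """
    K_apoplast = np.asarray(K_apoplast, dtype=float)
    if np.any(K_apoplast <= 0) or K_cytosol_ref <= 0:
        raise KineticsValidationError("K concentrations must be positive")
    return (GAS_CONSTANT * T / FARADAY) * np.log(K_apoplast / K_cytosol_ref) + offset


def nscc_permeability(P_base, Ca_ext, K_Ca):
    """External-Ca(2+) block of nonselective cation channels (single site).

    P_eff = P_base * K_Ca / (K_Ca + Ca_ext): full permeability without Ca,
    half block at Ca_ext = K_Ca, monotone decreasing.
    """
    return np.asarray(P_base, dtype=float) * K_Ca / (K_Ca + np.asarray(Ca_ext, dtype=float))


# ---------------------------------------------------------------------------
# antiporters


def antiporter_flux(k_ap, Na_in, Na_out, H_in, H_out):
    """1:1 Na+/H+ mass-action exchange (mol m^-2 s^-1, positive = Na+ efflux).

    J_Na = k_ap * (Na_in * H_out - Na_out * H_in); the coupled H+ flux is
    -J_Na and the net charge flux is exactly zero.
    """
    return np.asarray(k_ap, dtype=float) * (
        np.asarray(Na_in, dtype=float) * np.asarray(H_out, dtype=float)
        - np.asarray(Na_out, dtype=float) * np.asarray(H_in, dtype=float)
    )


# ---------------------------------------------------------------------------
# four-state carrier cycles


@dataclass
class CarrierCycleParams:
    """Four-state carrier cycle: 1 -(bind in)-> 2 -(translocate)-> 3
    -(release out)-> 4 -(return)-> 1; forward traversal carries the cargo out
    of the cytosol (positive flux).

    ``rates`` holds the eight base rate constants (k12, k21, k23, k32, k34,
    k43, k41, k14); entries named in ``binding`` are pseudo-first-order and
    are multiplied by the matching substrate concentration at evaluation
    time.  ``z_t`` elementary charges cross the membrane on the 2->3 step,
    which receives symmetric Eyring factors exp(+-z_t F V / 2RT).
    """

    rates: dict[str, float]
    N: float  # carrier surface density, mol m^-2
    z_t: float = 0.0
    binding: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # e.g. {"k12": [("H", "in")], "k43": [("H", "out")]}
    cargo: dict[str, float] = field(default_factory=dict)
    # species -> stoichiometry transported outward per forward cycle

    def __post_init__(self):
        expected = {"k12", "k21", "k23", "k32", "k34", "k43", "k41", "k14"}
        if set(self.rates) != expected:
            raise KineticsValidationError(f"rates must have keys {sorted(expected)}")
        if any(v < 0 for v in self.rates.values()) or self.N < 0:
            raise KineticsValidationError("rate constants and N must be >= 0")


_RATE_ORDER = ("k12", "k21", "k23", "k32", "k34", "k43", "k41", "k14")


def king_altman_flux(k12, k21, k23, k32, k34, k43, k41, k14, N=1.0):
    """Steady-state net cycle flux of a four-state single-cycle carrier.

    J = N * (k12 k23 k34 k41 - k21 k32 k43 k14) / Sigma, with Sigma the
    King-Altman sum of the 16 directed spanning-tree products.  Vanishes
    under detailed balance and is linear in the carrier density N.
    """
    ks = [np.asarray(k, dtype=float) for k in (k12, k21, k23, k32, k34, k43, k41, k14)]
    k12, k21, k23, k32, k34, k43, k41, k14 = ks
    # directed trees toward each state (cyclic rotation of the state-1 set)
    d1 = k21 * k32 * k43 + k23 * k34 * k41 + k21 * k34 * k41 + k21 * k32 * k41
    d2 = k32 * k43 * k14 + k34 * k41 * k12 + k32 * k41 * k12 + k32 * k43 * k12
    d3 = k43 * k14 * k21 + k41 * k12 * k23 + k43 * k12 * k23 + k43 * k14 * k23
    d4 = k14 * k21 * k32 + k12 * k23 * k34 + k14 * k23 * k34 + k14 * k21 * k34
    sigma = d1 + d2 + d3 + d4
    num = k12 * k23 * k34 * k41 - k21 * k32 * k43 * k14
    with np.errstate(invalid="ignore", divide="ignore"):
        J = N * np.where(sigma > 0, num / np.where(sigma > 0, sigma, 1.0), 0.0)
    return J


def carrier_cycle_rates(params: CarrierCycleParams, V, concentrations, T=TEMPERATURE):
    """Effective rates: binding steps scaled by substrate concentrations and
    the translocation step by the symmetric voltage factors.

    ``concentrations`` maps species -> {"in": c_in, "out": c_out}.
    """
    eff = {}
    for name in _RATE_ORDER:
        k = params.rates[name]
        for species, side in params.binding.get(name, ()):
            k = k * np.asarray(concentrations[species][side], dtype=float)
        eff[name] = k
    if params.z_t != 0.0:
        f = np.exp(
            np.clip(params.z_t * FARADAY * np.asarray(V, dtype=float)
                    / (2.0 * GAS_CONSTANT * T), -200, 200)
        )
        eff["k23"] = eff["k23"] * f
        eff["k32"] = eff["k32"] / f
    return eff


def carrier_cycle_flux(params: CarrierCycleParams, V, concentrations, T=TEMPERATURE):
    """Steady-state cycle flux (mol m^-2 s^-1, positive = cargo efflux)."""
    eff = carrier_cycle_rates(params, V, concentrations, T)
    return king_altman_flux(*[eff[n] for n in _RATE_ORDER], N=params.N)


def carrier_charge_flux(params: CarrierCycleParams, J_cycle):
    """Net charge flux (mol-equivalents m^-2 s^-1) carried by the cycle."""
    return params.z_t * np.asarray(J_cycle, dtype=float)


# ---------------------------------------------------------------------------
# water


def water_flux_plasma_membrane(Lp, sigma, P_in, P_out, pi_in, pi_out):
    """Kedem-Katchalsky volume flux (m s^-1, positive = out of the cell):
    Jv = Lp [ (P_in - P_out) - sigma (pi_in - pi_out) ]."""
    return np.asarray(Lp, dtype=float) * (
        (np.asarray(P_in, dtype=float) - np.asarray(P_out, dtype=float))
        - np.asarray(sigma, dtype=float)
        * (np.asarray(pi_in, dtype=float) - np.asarray(pi_out, dtype=float))
    )


def water_flux_tonoplast(Lp, sigma, pi_in, pi_out):
    """Tonoplast volume flux: osmotic term only, Jv = -Lp sigma (pi_in - pi_out).

    Positive flux moves water from the cytosol into the vacuole; the
    hydraulic term is excluded by construction (the tonoplast bears no
    pressure difference in this model).
    """
    return -np.asarray(Lp, dtype=float) * np.asarray(sigma, dtype=float) * (
        np.asarray(pi_in, dtype=float) - np.asarray(pi_out, dtype=float)
    )
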