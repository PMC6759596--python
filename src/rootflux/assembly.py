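"""Assembly of the coupled ion/water conservation system over the root.

State layout (``n`` compartments, deterministic geometry order): the state
vector stacks, species-major, the *reference-volume-scaled* amounts
``c_hat = (moles in compartment) / V0`` for Na+, K+, Cl- and total H (free +
buffer-bound), followed by the relative volume ``v = V / V0``:

    y = [c_hat_Na (n) | c_hat_K (n) | c_hat_Cl (n) | c_hat_H (n) | v (n)]

Actual concentrations are ``c = c_hat / v``; evolving scaled amounts makes
the conservation statement d(c V)/dt = sum(flux * area) exact by
construction.

Electric potentials are not independent states.  Each compartment carries a
small electric capacitance (``ModelParams.c_membrane`` per unit incident
membrane area), so its potential is an explicit function of the accumulated
net charge:

    phi_i = F * V_i * rho_i / C_i,

with ``rho`` the net charge density (mol-equiv m^-3).  Conductive pathways
then drain any charge imbalance within milliseconds, which enforces local
electroneutrality up to the documented residual bound
(:meth:`RootModel.electroneutrality_tolerance`) while keeping the system an
ordinary (stiff) ODE — the regularized form of the index-1 DAE with
algebraic potentials.  Hydraulic pressures are likewise explicit:
``P = eps * (v - 1)`` with a near-rigid modulus for wall compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
from scipy import sparse

from .constants import FARADAY, GAS_CONSTANT, SPECIES, VALENCE
from .geometry import EXTERNAL, SHOOT, ConnectivityGraph, RootGeometry
from .kinetics import (
    antiporter_flux,
    boltzmann_open_probability,
    carrier_cycle_flux,
    ghk_flux,
    kor_gating_midpoint,
    nscc_permeability,
    water_flux_plasma_membrane,
    water_flux_tonoplast,
)
from .parameters import BoundaryConditions, ModelParams, TransporterDistribution, ph_to_conc


class AssemblyError(RuntimeError):
    """Raised when the assembled system produces non-finite fluxes."""


def nernst_planck_edge_flux(D, z, c_a, c_b, phi_a, phi_b, length, v=0.0):
    """Two-point finite-volume Nernst-Planck flux along an edge
    (mol m^-2 s^-1, positive a -> b).

    J = -D [ (c_b - c_a)/L + z (F/RT) c_mean (phi_b - phi_a)/L ] + c_up * v,
    with the arithmetic interface mean and first-order upwinding of the
    convective term (``v`` is the water velocity a -> b in m s^-1).
    """
    L = np.asarray(length, dtype=float)
    if np.any(L <= 0):
        raise ValueError("edge length must be > 0")
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    dphi = (np.asarray(phi_b, dtype=float) - np.asarray(phi_a, dtype=float)) / L
    J = -np.asarray(D, dtype=float) * (
        (c_b - c_a) / L
        + z * FARADAY / (GAS_CONSTANT * 298.15) * 0.5 * (c_a + c_b) * dphi
    )
    v = np.asarray(v, dtype=float)
    c_up = np.where(v >= 0, c_a, c_b)
    return J + c_up * v


def proton_buffer_partition(H_total, B_total, K_b):
    """Split total H into free and single-buffer-bound parts.

    Solves H_free + B H_free/(K_b + H_free) = H_total for the positive root
    of the quadratic; H_free is strictly increasing in H_total and reduces to
    H_total when B_total = 0.  Returns (H_free, H_bound).
    """
    H_total = np.asarray(H_total, dtype=float)
    B = np.asarray(B_total, dtype=float)
    K_b = np.asarray(K_b, dtype=float)
    b = K_b + B - H_total
    disc = b * b + 4.0 * K_b * H_total
    sq = np.sqrt(disc)
    # numerically stable positive root for either sign of b
    H_free = np.where(b >= 0, 2.0 * K_b * H_total / (b + sq), 0.5 * (sq - b))
    H_free = np.minimum(H_free, H_total)
    return H_free, H_total - H_free


# ---------------------------------------------------------------------------


@dataclass
class _EdgeGroup:
    a: np.ndarray  # gather index (virtual slots included)
    b: np.ndarray
    area: np.ndarray
    length: np.ndarray
    kh: np.ndarray  # hydraulic coefficient (wall law) or 0
    is_pd: np.ndarray  # plasmodesma mask (Kedem-Katchalsky water law)
    tort: np.ndarray  # diffusive tortuosity factor (0 disables diffusion)


class RootModel:
    """The assembled root: geometry + connectivity + parameters + placements.

    The model is a pure right-hand-side factory: :meth:`rhs` maps
    ``(t, y, bc)`` to ``dy/dt`` and every observable is recomputable from a
    stored state via :meth:`fields` / :meth:`fluxes`.
    """

    def __init__(
        self,
        geometry: RootGeometry,
        graph: ConnectivityGraph,
        params: ModelParams,
        distribution: TransporterDistribution,
        bc: BoundaryConditions,
    ):
        self.geometry = geometry
        self.graph = graph
        self.params = params
        self.distribution = distribution
        self.bc = bc
        self._build()

    # -- construction --------------------------------------------------------

    def _build(self):
        g, p = self.geometry, self.params
        n = g.n_compartments
        self.n = n
        self.n_state = 5 * n
        self.EXT, self.SHT = n, n + 1  # virtual gather slots

        self.V0 = np.array([c.volume for c in g.compartments])
        self.layer = np.array([c.layer for c in g.compartments])
        self.ring = np.array([c.ring for c in g.compartments])
        kind_code = {"apoplast": 0, "cytosol": 1, "vacuole": 2}
        self.kind = np.array([kind_code[c.kind] for c in g.compartments])
        self.is_mature = self.layer >= g.apex_layers
        ring_names = [r.name for r in g.rings]
        self.tissue = np.array([ring_names[c.ring] for c in g.compartments])
        self.is_conduit = (
            (self.kind == 0) & self.is_mature & (self.tissue == "xylem")
        )

        self.eps = np.where(self.kind == 0, p.eps_apoplast, p.eps_cell)
        self.X0 = np.where(
            self.kind == 0,
            np.where(self.is_conduit, p.conduit_fixed_charge, p.apoplast_fixed_charge),
            0.0,
        )
        self.K_b = np.select(
            [self.kind == 1, self.kind == 2], [p.K_b_cytosol, p.K_b_vacuole], 1.0
        )

        # --- edge groups
        np_edges = []  # solute+water continuum edges
        pm = {"cyt": [], "apo": [], "area": [], "k_ap": [], "hkt": [],
              "zone": [], "tissue": [], "pump_scale": [], "nscc_scale": []}
        tono = {"cyt": [], "vac": [], "area": [], "nhx": []}
        mem_area_acc = np.zeros(n)

        def slot(i):
            return self.EXT if i == EXTERNAL else (self.SHT if i == SHOOT else i)

        for e in self.graph.edges:
            if e.blocked:
                continue
            if e.pathway in ("apoplast_radial", "apoplast_axial", "boundary_external",
                             "plasmodesma", "boundary_xylem_top"):
                ia, ib = slot(e.a), slot(e.b)
                both_conduit = (
                    e.pathway == "apoplast_axial"
                    and e.a >= 0 and e.b >= 0
                    and self.is_conduit[e.a] and self.is_conduit[e.b]
                )
                if e.pathway == "boundary_xylem_top":
                    kh, tort, is_pd = p.k_h_xylem, 0.0, False  # advective only
                elif e.pathway == "plasmodesma":
                    kh, tort, is_pd = 0.0, p.tortuosity_symplast, True
                elif both_conduit:
                    kh, tort, is_pd = p.k_h_xylem, p.tortuosity_xylem, False
                else:
                    kh, tort, is_pd = p.k_h_wall, p.tortuosity_wall, False
                np_edges.append((ia, ib, e.area, e.length, kh, is_pd, tort))
            elif e.pathway == "plasma_membrane":
                cyt, apo = e.a, e.b
                zone = g.zone_of_layer(g.compartments[cyt].layer)
                tissue = ring_names[g.compartments[cyt].ring]
                pm["cyt"].append(cyt)
                pm["apo"].append(apo)
                pm["area"].append(e.area)
                pm["k_ap"].append(self.distribution.k_ap_for(zone, tissue))
                pm["hkt"].append((zone, tissue) in self.distribution.hkt_locations)
                pm["zone"].append(zone)
                pm["tissue"].append(tissue)
                pm["pump_scale"].append(
                    p.pump_density_stele_scale
                    if tissue in ("xylem_parenchyma", "xylem") else 1.0
                )
                pm["nscc_scale"].append(
                    p.nscc_apex_scale if zone == "apex" else 1.0
                )
                mem_area_acc[cyt] += e.area
                mem_area_acc[apo] += e.area
            elif e.pathway == "tonoplast":
                cyt, vac = e.a, e.b
                zone = g.zone_of_layer(g.compartments[cyt].layer)
                tono["cyt"].append(cyt)
                tono["vac"].append(vac)
                tono["area"].append(e.area)
                tono["nhx"].append(zone in self.distribution.tono_nhx_zones)
                mem_area_acc[cyt] += e.area
                mem_area_acc[vac] += e.area

        def arr(x, dtype=float):
            return np.asarray(x, dtype=dtype)

        ne = len(np_edges)
        self.np_edges = _EdgeGroup(
            a=arr([e[0] for e in np_edges], int),
            b=arr([e[1] for e in np_edges], int),
            area=arr([e[2] for e in np_edges]),
            length=arr([e[3] for e in np_edges]),
            kh=arr([e[4] for e in np_edges]),
            is_pd=arr([e[5] for e in np_edges], bool),
            tort=arr([e[6] for e in np_edges]),
        ) if ne else None
        def pm_dtype(k):
            if k == "hkt":
                return bool
            if k in ("cyt", "apo"):
                return int
            if k in ("zone", "tissue"):
                return object
            return float

        self.pm = {k: np.asarray(v, dtype=pm_dtype(k)) for k, v in pm.items()} \
            if pm["cyt"] else None
        self.tono = {k: arr(v, bool if k == "nhx" else (int if k in ("cyt", "vac") else float))
                     for k, v in tono.items()} if tono["cyt"] else None

        # top-of-xylem edge index within the NP group (for observables)
        self.top_edge = None
        if self.np_edges is not None:
            tops = np.where(self.np_edges.b == self.SHT)[0]
            if tops.size:
                self.top_edge = int(tops[0])

        # --- pressure groups: the cell wall confines the whole protoplast,
        # so a cytosol and its vacuole share one elastic turgor pressure
        # computed from their combined volume; apoplast compartments stand
        # alone with the near-rigid wall modulus.
        group_of: dict[tuple[int, int, str], int] = {}
        pgroup = np.empty(n, dtype=int)
        for i, comp in enumerate(g.compartments):
            key = (comp.layer, comp.ring, "cell" if comp.kind != "apoplast" else "apo")
            if key not in group_of:
                group_of[key] = len(group_of)
            pgroup[i] = group_of[key]
        self.pgroup = pgroup
        self.n_pgroups = len(group_of)
        self.pgroup_V0 = np.bincount(pgroup, weights=self.V0, minlength=self.n_pgroups)

        # --- capacitance / potential scale
        sphere = (36.0 * np.pi) ** (1.0 / 3.0) * self.V0 ** (2.0 / 3.0)
        C = p.c_membrane * np.maximum(mem_area_acc, sphere)
        self.kappa = FARADAY * self.V0 / C  # phi = kappa * v * rho

        # carrier-cycle parameter sets (shared across membranes)
        self._pm_pump = p.pm_pump()
        self._tono_pump = p.tono_pump()
        self._kh_sym = p.kh_symporter_params()
        self._clh_sym = p.clh_symporter_params()

        self._build_initial()

    def _build_initial(self):
        """Exactly electroneutral initial guess; the cytosolic/vacuolar
        proton buffer doubles as the impermeant anion background, so its
        density is set here to close the charge balance."""
        g, p, bc = self.geometry, self.params, self.bc
        n = self.n
        c0 = {s: np.zeros(n) for s in SPECIES}
        ext = bc.conc

        apo = self.kind == 0
        cyt = self.kind == 1
        vac = self.kind == 2

        # apoplast: external cations, Cl chosen electroneutral (the medium's
        # Ca-balanced chloride has no internal counter-cation), plus cations
        # compensating the fixed wall charge
        wNa = ext["Na"] / max(ext["Na"] + ext["K"], 1e-12) if (ext["Na"] + ext["K"]) > 0 else 0.0
        c0["Na"][apo] = ext["Na"] + self.X0[apo] * wNa
        c0["K"][apo] = ext["K"] + self.X0[apo] * (1.0 - wNa)
        c0["H"][apo] = ext["H"]
        c0["Cl"][apo] = ext["Na"] + ext["K"] + ext["H"]

        for s in ("Na", "K", "Cl"):
            c0[s][cyt] = p.init_cytosol[s]
            c0[s][vac] = p.init_vacuole[s]

        H_free_cyt = ph_to_conc(p.pH_cytosol_init)
        H_free_vac = ph_to_conc(p.pH_vacuole_init)
        H_free = np.where(cyt, H_free_cyt, np.where(vac, H_free_vac, c0["H"]))

        # buffer density closing electroneutrality in cells
        B0 = np.zeros(n)
        cells = cyt | vac
        need = (c0["Na"] + c0["K"] + H_free - c0["Cl"])[cells]
        if np.any(need <= 0):
            raise AssemblyError(
                "initial cell composition leaves no room for the anionic buffer"
            )
        Kb = self.K_b[cells]
        B0[cells] = need * (Kb + H_free[cells]) / Kb
        self.B0 = B0
        H_bound = B0 * H_free / (self.K_b + H_free)
        c0["H"] = np.where(cells, H_free + H_bound, c0["H"])

        y0 = np.concatenate([c0[s] for s in SPECIES] + [np.ones(n)])
        self.y0 = y0

    # -- state access --------------------------------------------------------

    def unpack(self, y):
        n = self.n
        c_hat = {s: y[i * n:(i + 1) * n] for i, s in enumerate(SPECIES)}
        v = y[4 * n:5 * n]
        return c_hat, v

    def fields(self, y, bc: BoundaryConditions | None = None):
        """All derived per-compartment fields, with the two virtual boundary
        slots (external medium, shoot) appended for uniform edge gathers."""
        bc = bc or self.bc
        p = self.params
        RT = GAS_CONSTANT * p.T
        c_hat, v = self.unpack(y)
        v_safe = np.maximum(v, 0.05)
        c = {s: np.maximum(c_hat[s], 0.0) / v_safe for s in SPECIES}
        B = self.B0 / v_safe
        X = self.X0 / v_safe
        H_free, H_bound = proton_buffer_partition(c["H"], B, self.K_b)
        B_free = B - H_bound
        rho = c["Na"] + c["K"] + H_free - c["Cl"] - B_free - X
        phi = self.kappa * v_safe * rho
        # shared turgor per pressure group (whole-protoplast elasticity)
        Vg = np.bincount(self.pgroup, weights=v * self.V0, minlength=self.n_pgroups)
        v_group = (Vg / self.pgroup_V0)[self.pgroup]
        P = self.eps * (v_group - 1.0) + bc.P_external
        pi = RT * (c["Na"] + c["K"] + c["Cl"] + H_free + B + X)

        ext = bc.conc
        full = SimpleNamespace()
        full.c = {}
        for s in SPECIES:
            vals = np.empty(self.n + 2)
            vals[: self.n] = c[s]
            vals[self.EXT] = ext[s]
            # shoot slot mirrors the top conduit so backflow is neutral
            vals[self.SHT] = c[s][self._top_comp()] if self.top_edge is not None else 0.0
            full.c[s] = vals
        full.H_free = np.concatenate([H_free, [ext["H"], ext["H"]]])
        full.phi = np.concatenate([phi, [0.0, 0.0]])
        full.P = np.concatenate([P, [bc.P_external, bc.P_shoot]])
        pi_ext = bc.osmotic_pressure(p.T)
        full.pi = np.concatenate([pi, [pi_ext, 0.0]])
        full.rho = rho
        full.v = v
        full.v_safe = v_safe
        full.H_bound = H_bound
        return full

    def _top_comp(self) -> int:
        return int(self.np_edges.a[self.top_edge])

    # -- physics -------------------------------------------------------------

    def _np_water_flux(self, f):
        """Volume flow q (m^3/s, a->b) on every continuum edge."""
        e = self.np_edges
        Pa, Pb = f.P[e.a], f.P[e.b]
        q_wall = -e.kh * (Pb - Pa) / e.length * e.area
        pia, pib = f.pi[e.a], f.pi[e.b]
        q_pd = self.params.Lp_pd * (
            (Pa - Pb) - self.params.sigma_pd * (pia - pib)
        ) * e.area
        return np.where(e.is_pd, q_pd, q_wall)

    @staticmethod
    def _bernoulli(x):
        """B(x) = x / (e^x - 1), smooth (B(0) = 1), with stable asymptotics
        B(x) -> -x for x << 0 and B(x) -> x e^-x for x >> 0."""
        x = np.asarray(x, dtype=float)
        small = np.abs(x) < 1e-8
        lo = x < -30.0
        hi = x > 30.0
        mid = ~(small | lo | hi)
        out = np.empty_like(x)
        out[small] = 1.0 - 0.5 * x[small]
        out[lo] = -x[lo]
        xh = np.minimum(x[hi], 700.0)
        out[hi] = x[hi] * np.exp(-xh)
        out[mid] = x[mid] / np.expm1(x[mid])
        return out

    def _np_solute_flux(self, f, q):
        """Molar flow (mol/s, a->b) per species on every continuum edge.

        Exponentially fitted (Scharfetter-Gummel) two-point scheme for the
        combined diffusion + electromigration + convection flux: smooth in
        all states (unlike hard upwinding) and monotone in the
        advection-dominated xylem conduit.
        """
        e = self.np_edges
        p = self.params
        RT = GAS_CONSTANT * p.T
        u = q / e.area  # water velocity a->b
        dphi = f.phi[e.b] - f.phi[e.a]
        conc_all = np.vstack([f.c["Na"], f.c["K"], f.c["Cl"], f.H_free])
        ca, cb = conc_all[:, e.a], conc_all[:, e.b]
        z = np.array([[VALENCE[s]] for s in SPECIES], dtype=float)
        D0 = np.array([[p.D_free[s]] for s in SPECIES])
        D = D0 * e.tort
        diffusive = D > 0
        D_safe = np.where(diffusive, D, 1.0)
        # drift velocity: convection plus migration
        w = u - z * FARADAY / RT * D * dphi / e.length
        Pe = w * e.length / D_safe
        J_sg = (D_safe / e.length) * (
            self._bernoulli(-Pe) * ca - self._bernoulli(Pe) * cb
        )
        # purely advective edges (D = 0, e.g. the xylem-top outflow): upwind
        J_adv = np.where(u >= 0, ca, cb) * u
        J = np.where(diffusive, J_sg, J_adv) * e.area
        return {s: J[i] for i, s in enumerate(SPECIES)}

    def _pm_fluxes(self, f, bc):
        """Per-membrane molar fluxes (mol m^-2 s^-1, positive = efflux from
        the cytosol) and the water volume flux, for every plasma membrane."""
        p = self.params
        m = self.pm
        ci, ai = m["cyt"], m["apo"]
        Vm = f.phi[ci] - f.phi[ai]
        conc = {s: {"in": f.c[s][ci], "out": f.c[s][ai]} for s in ("Na", "K", "Cl")}
        conc["H"] = {"in": f.H_free[ci], "out": f.H_free[ai]}

        J = {s: np.zeros(len(ci)) for s in SPECIES}

        # all GHK channels evaluated in one stacked call:
        # rows: NSCC(Na), NSCC(K), KIR(K), KOR(K), HKT(Na), anion(Cl), leak(H)
        P_nscc = nscc_permeability(p.P_nscc, bc.Ca, p.K_Ca) * m["nscc_scale"]
        p_kir = boltzmann_open_probability(Vm, p.kir_V_half, p.kir_slope, "inward")
        vh = kor_gating_midpoint(
            np.maximum(conc["K"]["out"], 1e-6), p.K_cytosol_ref, p.kor_offset, p.T
        )
        p_kor = boltzmann_open_probability(Vm, vh, p.kor_slope, "outward")
        ones = np.ones(len(ci))
        P_stack = np.vstack([
            P_nscc, P_nscc, p.P_kir * p_kir, p.P_kor * p_kor,
            np.where(m["hkt"], p.P_hkt, 0.0), p.P_anion_pm * ones, p.P_h_pm * ones,
        ])
        z_stack = np.array([[1.0], [1.0], [1.0], [1.0], [1.0], [-1.0], [1.0]])
        cin = np.vstack([conc["Na"]["in"], conc["K"]["in"], conc["K"]["in"],
                         conc["K"]["in"], conc["Na"]["in"], conc["Cl"]["in"],
                         conc["H"]["in"]])
        cout = np.vstack([conc["Na"]["out"], conc["K"]["out"], conc["K"]["out"],
                          conc["K"]["out"], conc["Na"]["out"], conc["Cl"]["out"],
                          conc["H"]["out"]])
        Jg = ghk_flux(P_stack, z_stack, Vm, cin, cout, p.T)
        J["Na"] += Jg[0] + Jg[4]
        J["K"] += Jg[1] + Jg[2] + Jg[3]
        J["Cl"] += Jg[5]
        J["H"] += Jg[6]

        J_pump = carrier_cycle_flux(self._pm_pump, Vm, conc, p.T) * m["pump_scale"]
        J["H"] += J_pump

        J_kh = carrier_cycle_flux(self._kh_sym, Vm, conc, p.T)
        J["K"] += J_kh
        J["H"] += J_kh

        J_clh = carrier_cycle_flux(self._clh_sym, Vm, conc, p.T)
        J["Cl"] += J_clh
        J["H"] += 2.0 * J_clh

        J_ap = antiporter_flux(
            m["k_ap"], conc["Na"]["in"], conc["Na"]["out"],
            conc["H"]["in"], conc["H"]["out"],
        )
        J["Na"] += J_ap
        J["H"] -= J_ap

        Jv = water_flux_plasma_membrane(
            p.Lp_pm, p.sigma_pm, f.P[ci], f.P[ai], f.pi[ci], f.pi[ai]
        )
        return J, Jv, {"antiporter_Na": J_ap, "pump_H": J_pump, "Vm": Vm}

    def _tono_fluxes(self, f):
        """Tonoplast fluxes, positive = from cytosol into vacuole."""
        p = self.params
        m = self.tono
        ci, vi = m["cyt"], m["vac"]
        Vm = f.phi[ci] - f.phi[vi]
        conc = {s: {"in": f.c[s][ci], "out": f.c[s][vi]} for s in ("Na", "K", "Cl")}
        conc["H"] = {"in": f.H_free[ci], "out": f.H_free[vi]}

        J = {s: np.zeros(len(ci)) for s in SPECIES}
        P_stack = np.array([[p.P_tono_na], [p.P_tono_k], [p.P_tono_cl], [p.P_tono_h]])
        z_stack = np.array([[1.0], [1.0], [-1.0], [1.0]])
        cin = np.vstack([conc[s]["in"] for s in SPECIES])
        cout = np.vstack([conc[s]["out"] for s in SPECIES])
        Jg = ghk_flux(P_stack, z_stack, Vm, cin, cout, p.T)
        for i, s in enumerate(SPECIES):
            J[s] += Jg[i]

        J_pump = carrier_cycle_flux(self._tono_pump, Vm, conc, p.T)
        J["H"] += J_pump

        J_nhx = antiporter_flux(
            np.where(m["nhx"], p.k_ap_tono_na, 0.0),
            conc["Na"]["in"], conc["Na"]["out"], conc["H"]["in"], conc["H"]["out"],
        )
        J["Na"] += J_nhx
        J["H"] -= J_nhx

        J_khx = antiporter_flux(
            p.k_ap_tono_k, conc["K"]["in"], conc["K"]["out"],
            conc["H"]["in"], conc["H"]["out"],
        )
        J["K"] += J_khx
        J["H"] -= J_khx

        Jv = water_flux_tonoplast(p.Lp_tonoplast, p.sigma_tonoplast, f.pi[ci], f.pi[vi])
        return J, Jv, {"nhx_Na": J_nhx, "Vm": Vm}

    # -- RHS -----------------------------------------------------------------

    def rhs(self, t, y, bc: BoundaryConditions | None = None):
        bc = bc or self.bc
        f = self.fields(y, bc)
        n = self.n
        nv = n + 2
        dmol = {s: np.zeros(nv) for s in SPECIES}  # mol/s into each compartment
        dvol = np.zeros(nv)  # m^3/s

        def acc(target, ia, ib, flow):
            np.add.at(target, ia, -flow)
            np.add.at(target, ib, flow)

        if self.np_edges is not None:
            e = self.np_edges
            q = self._np_water_flux(f)
            acc(dvol, e.a, e.b, q)
            sol = self._np_solute_flux(f, q)
            for s in SPECIES:
                acc(dmol[s], e.a, e.b, sol[s])

        if self.pm is not None:
            J, Jv, _ = self._pm_fluxes(f, bc)
            A = self.pm["area"]
            ci, ai = self.pm["cyt"], self.pm["apo"]
            for s in SPECIES:
                acc(dmol[s], ci, ai, J[s] * A)
            acc(dvol, ci, ai, Jv * A)

        if self.tono is not None:
            J, Jv, _ = self._tono_fluxes(f)
            A = self.tono["area"]
            ci, vi = self.tono["cyt"], self.tono["vac"]
            for s in SPECIES:
                acc(dmol[s], ci, vi, J[s] * A)
            acc(dvol, ci, vi, Jv * A)

        dy = np.concatenate(
            [dmol[s][:n] / self.V0 for s in SPECIES] + [dvol[:n] / self.V0]
        )
        if not np.all(np.isfinite(dy)):
            bad = np.where(~np.isfinite(dy))[0]
            i = bad[0] % n
            s = ("Na", "K", "Cl", "H", "volume")[bad[0] // n]
            c = self.geometry.compartments[i]
            raise AssemblyError(
                f"non-finite rate for {s} in compartment {i} "
                f"(layer {c.layer}, ring {c.ring}, {c.kind}) at t={t:.3g}"
            )
        return dy

    # -- diagnostics -----------------------------------------------------------

    def electroneutrality_residual(self, y, bc=None):
        """Per-compartment net charge density (mol-equiv m^-3)."""
        return self.fields(y, bc).rho

    def electroneutrality_tolerance(self, phi_max: float = 0.35):
        """Residual bound implied by the capacitive regularization: the
        charge density needed to hold a potential of ``phi_max``."""
        return phi_max / self.kappa

    def fluxes(self, y, bc: BoundaryConditions | None = None):
        """Full flux breakdown at a state (pure function, for observables)."""
        bc = bc or self.bc
        f = self.fields(y, bc)
        out = SimpleNamespace(fields=f)
        if self.np_edges is not None:
            out.q_np = self._np_water_flux(f)
            out.J_np = self._np_solute_flux(f, out.q_np)
        if self.pm is not None:
            out.J_pm, out.Jv_pm, out.pm_extra = self._pm_fluxes(f, bc)
        if self.tono is not None:
            out.J_tono, out.Jv_tono, out.tono_extra = self._tono_fluxes(f)
        return out

    def jac_sparsity(self) -> sparse.csr_matrix:
        """Conservative Jacobian sparsity: full 5x5 coupling within a
        compartment and across every unblocked edge."""
        n = self.n
        rows, cols = [np.arange(n)], [np.arange(n)]
        pairs = []
        if self.np_edges is not None:
            m = (self.np_edges.a < n) & (self.np_edges.b < n)
            pairs.append((self.np_edges.a[m], self.np_edges.b[m]))
        if self.pm is not None:
            pairs.append((self.pm["cyt"], self.pm["apo"]))
        if self.tono is not None:
            pairs.append((self.tono["cyt"], self.tono["vac"]))
        for a, b in pairs:
            rows.extend([a, b])
            cols.extend([b, a])
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        adj = sparse.coo_matrix(
            (np.ones_like(r, dtype=np.int8), (r, c)), shape=(n, n)
        ).tocsr()
        # shared turgor: every flux that reads a compartment's pressure also
        # depends on the volumes of its whole pressure group, so compose the
        # edge adjacency with the group-membership coupling
        gidx = np.arange(n)
        G = sparse.coo_matrix(
            (np.ones(n, dtype=np.int8), (gidx, self.pgroup)),
            shape=(n, self.n_pgroups),
        ).tocsr()
        group_couple = (G @ G.T).astype(bool).astype(np.int8)  # same-group pairs
        full = adj + adj @ group_couple + group_couple @ adj + group_couple
        full.data[:] = 1
        return sparse.kron(np.ones((5, 5), dtype=np.int8), full).tocsr()

    def state_table(self, y, bc=None) -> "pd.DataFrame":
        """Columnar snapshot (one row per compartment and quantity)."""
        import pandas as pd

        f = self.fields(y, bc)
        g = self.geometry
        rows = []
        for i, comp in enumerate(g.compartments):
            base = {
                "compartment": i,
                "layer": comp.layer,
                "ring": comp.ring,
                "kind": comp.kind,
                "zone": g.zone_of_layer(comp.layer),
            }
            for s in SPECIES:
                rows.append({**base, "quantity": f"c_{s}", "value": f.c[s][i]})
            rows.append({**base, "quantity": "H_free", "value": f.H_free[i]})
            rows.append({**base, "quantity": "phi", "value": f.phi[i]})
            rows.append({**base, "quantity": "P", "value": f.P[i]})
            rows.append({**base, "quantity": "volume", "value": f.v[i] * self.V0[i]})
        return pd.DataFrame(rows)
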