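"""Time integration, salt-step protocols, and observable extraction.

The stiff system is integrated with the variable-order BDF method
(``scipy.integrate.solve_ivp``), the Python analogue of the MATLAB stiff
solver family, using the model's Jacobian sparsity pattern.  A salt exposure
is a boundary-condition switch at ``salt_onset`` (instantaneous by default,
optionally ramped); "day d" observables refer to ``salt_onset + d * 86400 s``.

Every observable is a pure function of a stored trajectory snapshot: it is
recomputed from the state vector through the model's flux breakdown, so
serialized trajectories can be re-analyzed offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize._numdiff import approx_derivative, group_columns

from .assembly import RootModel
from .constants import SPECIES, WATER_DENSITY
from .parameters import BoundaryConditions
from .units import mol_s_kg_to_nmol_min_g


class ConvergenceError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass
class Protocol:
    """A pre-salt medium, a salt medium, and the exposure timing."""

    pre_salt: BoundaryConditions
    salt: BoundaryConditions
    salt_onset: float = 0.0
    duration: float = 86400.0
    output_times: list = field(default_factory=list)
    ramp: float = 0.0  # s over which the salt step is linearly applied

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("protocol duration must be > 0")
        ts = sorted(self.output_times)
        if ts and (ts[0] < 0 or ts[-1] > self.duration):
            raise ValueError("output times must lie within [0, duration]")
        self.output_times = ts

    def bc_at(self, t: float) -> BoundaryConditions:
        if t < self.salt_onset:
            return self.pre_salt
        if self.ramp > 0 and t < self.salt_onset + self.ramp:
            w = (t - self.salt_onset) / self.ramp
            return replace(
                self.salt,
                NaCl=self.pre_salt.NaCl + w * (self.salt.NaCl - self.pre_salt.NaCl),
            )
        return self.salt


@dataclass
class Trajectory:
    """Times, state snapshots, and the protocol that produced them."""

    model: RootModel
    times: np.ndarray
    states: np.ndarray  # (n_times, n_state)
    protocol: Protocol | None = None
    bc: BoundaryConditions | None = None  # for single-medium runs
    diagnostics: dict = field(default_factory=dict)

    def bc_at(self, t: float) -> BoundaryConditions:
        if self.protocol is not None:
            return self.protocol.bc_at(t)
        return self.bc or self.model.bc

    def state_at(self, t: float) -> np.ndarray:
        ts = self.times
        if t <= ts[0]:
            return self.states[0]
        if t >= ts[-1]:
            return self.states[-1]
        i = int(np.searchsorted(ts, t))
        w = (t - ts[i - 1]) / (ts[i] - ts[i - 1])
        return (1 - w) * self.states[i - 1] + w * self.states[i]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t, y in zip(self.times, self.states):
            df = self.model.state_table(y, self.bc_at(t))
            df.insert(0, "time_s", t)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _atol_vector(model: RootModel, atol: float) -> np.ndarray:
    scale = np.maximum(np.abs(model.y0), 1.0)
    return atol * scale


def integrate(
    model: RootModel,
    y0: np.ndarray,
    t_span: tuple[float, float],
    bc=None,
    t_eval=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
):
    """Stiff BDF integration of the root model over ``t_span``.

    ``bc`` may be a :class:`BoundaryConditions` or a callable ``t -> bc``
    (used for ramped salt steps).
    """
    if callable(bc):
        fun = lambda t, y: model.rhs(t, y, bc(t))
    else:
        fun = lambda t, y: model.rhs(t, y, bc)

    # grouped finite-difference Jacobian on the model's sparsity pattern;
    # fixed relative steps are more robust here than the solver's adaptive
    # per-column factors, which misbehave on the widely scaled state vector
    sparsity = model.jac_sparsity()
    groups = group_columns(sparsity)

    def jac(t, y):
        return approx_derivative(
            lambda yy: fun(t, yy), y, method="2-point",
            sparsity=(sparsity, groups),
        )

    sol = solve_ivp(
        fun,
        t_span,
        y0,
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=_atol_vector(model, atol),
        jac=jac,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed at t={sol.t[-1] if sol.t.size else t_span[0]:.6g}: "
            f"{sol.message}"
        )
    return sol


def scaled_rate_norm(model: RootModel, y: np.ndarray, bc=None) -> float:
    """max_i |dy_i/dt| / max(|y_i|, 1) in s^-1 — the steady-state measure."""
    dy = model.rhs(0.0, y, bc)
    return float(np.max(np.abs(dy) / np.maximum(np.abs(y), 1.0)))


def solve_presalt_steady_state(
    model: RootModel,
    bc: BoundaryConditions | None = None,
    tol: float = 1e-9,
    t_stage: float = 2e6,
    max_stages: int = 6,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    y0: np.ndarray | None = None,
) -> np.ndarray:
    """Relax the model to its pre-salt steady state.

    Integrates from the documented uniform initial guess in geometrically
    growing stages until the scaled rate norm drops below ``tol`` (s^-1).
    """
    bc = bc or model.bc
    y = model.y0.copy() if y0 is None else y0.copy()
    if scaled_rate_norm(model, y, bc) < tol:
        return y
    t0, dt = 0.0, t_stage
    for _ in range(max_stages):
        sol = integrate(model, y, (t0, t0 + dt), bc, rtol=rtol, atol=atol)
        y = sol.y[:, -1]
        r = scaled_rate_norm(model, y, bc)
        if r < tol:
            return y
        t0 += dt
        dt *= 4.0
    raise ConvergenceError(
        f"no steady state within t={t0:.3g} s; scaled rate norm {r:.3g} > {tol:.3g}"
    )


def run_protocol(
    model: RootModel,
    y0: np.ndarray,
    protocol: Protocol,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Run a salt-exposure protocol from a consistent starting state."""
    times = np.asarray(protocol.output_times, dtype=float)
    if times.size == 0:
        times = np.array([0.0, protocol.duration])
    segs = []
    diagnostics = {"n_steps": 0}

    def collect(t0, t1, bc, y):
        mask = (times >= t0) & (times <= t1)
        t_eval = np.unique(np.concatenate([times[mask], [t0, t1]]))
        sol = integrate(model, y, (t0, t1), bc, t_eval=t_eval, rtol=rtol, atol=atol)
        diagnostics["n_steps"] += sol.t.size
        segs.append((sol.t, sol.y))
        return sol.y[:, -1]

    y = np.asarray(y0, dtype=float)
    t_cursor = 0.0
    if protocol.salt_onset > 0:
        y = collect(0.0, protocol.salt_onset, protocol.pre_salt, y)
        t_cursor = protocol.salt_onset
    if protocol.ramp > 0:
        t_ramp_end = min(protocol.salt_onset + protocol.ramp, protocol.duration)
        y = collect(t_cursor, t_ramp_end, protocol.bc_at, y)
        t_cursor = t_ramp_end
    if t_cursor < protocol.duration:
        collect(t_cursor, protocol.duration, protocol.salt, y)

    all_t = np.concatenate([t for t, _ in segs])
    all_y = np.concatenate([y.T for _, y in segs], axis=0)
    order = np.argsort(all_t, kind="stable")
    all_t, all_y = all_t[order], all_y[order]
    keep = np.concatenate([[True], np.diff(all_t) > 0])
    return Trajectory(
        model=model,
        times=all_t[keep],
        states=all_y[keep],
        protocol=protocol,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# observables


def root_ion_content_per_fw(traj: Trajectory, t: float, species: str) -> float:
    """Whole-root ion content, mol per kg fresh weight (total H for 'H')."""
    model = traj.model
    c_hat, _ = model.unpack(traj.state_at(t))
    return float(np.sum(c_hat[species] * model.V0) / model.geometry.total_fresh_weight)


def flux_to_shoot(traj: Trajectory, t: float, species: str) -> float:
    """Species flow through the top of the xylem conduit (mol s^-1)."""
    model = traj.model
    if model.top_edge is None:
        return 0.0
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    return float(fx.J_np[species][model.top_edge])


def flux_to_shoot_per_fw(traj: Trajectory, t: float, species: str) -> float:
    """As :func:`flux_to_shoot` but per kg fresh weight."""
    return flux_to_shoot(traj, t, species) / traj.model.geometry.total_fresh_weight


def flux_to_shoot_nmol_min_g(traj: Trajectory, t: float, species: str) -> float:
    return mol_s_kg_to_nmol_min_g(flux_to_shoot_per_fw(traj, t, species))


def water_flux_to_shoot(traj: Trajectory, t: float) -> float:
    """Volume flow through the top of the xylem conduit (m^3 s^-1)."""
    model = traj.model
    if model.top_edge is None:
        return 0.0
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    return float(fx.q_np[model.top_edge])


def surface_influx(traj: Trajectory, t: float, species: str) -> float:
    """Net species flow into the root across its entire external surface
    (mol s^-1, positive inward)."""
    model = traj.model
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    e = model.np_edges
    ext_edges = e.a == model.EXT
    return float(np.sum(fx.J_np[species][ext_edges]))


def epidermal_membrane_potential(traj: Trajectory, t: float, layer: int) -> float:
    """phi_cytosol - phi_apoplast of the epidermal cell in ``layer`` (V)."""
    model = traj.model
    f = model.fields(traj.state_at(t), traj.bc_at(t))
    g = model.geometry
    return float(f.phi[g.comp(layer, 0, "cytosol").index]
                 - f.phi[g.comp(layer, 0, "apoplast").index])


def mean_cytosolic_concentration(
    traj: Trajectory, t: float, zone: str, species: str
) -> float:
    """Volume-weighted mean cytosolic concentration over a zone (mol m^-3)."""
    model = traj.model
    f = model.fields(traj.state_at(t), traj.bc_at(t))
    mature = model.is_mature if zone == "mature" else ~model.is_mature
    sel = (model.kind == 1) & mature
    if not np.any(sel):
        raise ValueError(f"zone {zone!r} contains no cytosols")
    w = f.v[sel] * model.V0[sel]
    return float(np.sum(f.c[species][: model.n][sel] * w) / np.sum(w))


def zone_surface_efflux(traj: Trajectory, t: float, zone: str, species: str) -> float:
    """Net species efflux across the external surface of a zone, per kg of
    that zone's fresh weight (mol s^-1 kg^-1, positive = out of the root)."""
    model = traj.model
    g = model.geometry
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    e = model.np_edges
    ext = e.a == model.EXT
    out = 0.0
    for i in np.where(ext)[0]:
        comp = g.compartments[int(e.b[i])]
        if g.zone_of_layer(comp.layer) == zone:
            out -= fx.J_np[species][i]  # a->b positive is influx
    return out / g.zone_fresh_weight(zone)


def zone_tracer_efflux(traj: Trajectory, t: float, zone: str) -> float:
    """Unidirectional (tracer-visible) cellular Na+ efflux from the outer
    tissues of a zone, per kg of that zone's fresh weight (mol s^-1 kg^-1).

    A radiotracer wash-out experiment sees every outward plasma-membrane Na+
    flux regardless of the concurrent influx through other transporters on
    the same membrane.  The carrier-mediated (Na+/H+ antiporter) efflux is
    unidirectional by mechanism and is counted whenever it runs outward; the
    remaining (channel) flux is added when its net direction is outward.
    Contrast with :func:`zone_surface_efflux`, the *net* flux across the
    root surface.
    """
    model = traj.model
    if model.pm is None:
        return 0.0
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    outer = np.isin(model.pm["tissue"], ("epidermis", "cortex", "endodermis"))
    sel = (model.pm["zone"] == zone) & outer
    J_ap = fx.pm_extra["antiporter_Na"][sel]
    J_channels = fx.J_pm["Na"][sel] - J_ap
    A = model.pm["area"][sel]
    gross = np.sum((np.maximum(J_ap, 0.0) + np.maximum(J_channels, 0.0)) * A)
    return float(gross) / model.geometry.zone_fresh_weight(zone)


def antiporter_tissue_flux(traj: Trajectory, t: float, zone: str, tissue: str) -> float:
    """Summed Na+ flux through the plasma-membrane Na+/H+ antiporters of one
    tissue in one zone (mol s^-1, positive = out of the cytosol)."""
    model = traj.model
    if model.pm is None:
        return 0.0
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    sel = (model.pm["zone"] == zone) & (model.pm["tissue"] == tissue)
    return float(np.sum(fx.pm_extra["antiporter_Na"][sel] * model.pm["area"][sel]))


def antiporter_xylem_loading(traj: Trajectory, t: float) -> float:
    """Summed Na+ flux through plasma-membrane Na+/H+ antiporters of the
    mature xylem parenchyma (mol s^-1, positive = into the stelar apoplast;
    negative would mean the antiporters unload the xylem)."""
    model = traj.model
    if model.pm is None:
        return 0.0
    fx = model.fluxes(traj.state_at(t), traj.bc_at(t))
    sel = (model.pm["zone"] == "mature") & (model.pm["tissue"] == "xylem_parenchyma")
    return float(np.sum(fx.pm_extra["antiporter_Na"][sel] * model.pm["area"][sel]))


def antiporter_xylem_loading_per_fw(traj: Trajectory, t: float) -> float:
    return antiporter_xylem_loading(traj, t) / traj.model.geometry.total_fresh_weight


def xylem_sap_concentration(traj: Trajectory, t: float, species: str) -> float:
    """Concentration in the topmost functional xylem conduit (mol m^-3)."""
    model = traj.model
    if model.top_edge is None:
        raise ValueError("geometry has no functional xylem conduit")
    f = model.fields(traj.state_at(t), traj.bc_at(t))
    return float(f.c[species][model._top_comp()])


def observable_frame(traj: Trajectory, times=None) -> pd.DataFrame:
    """Tidy time series of the headline observables."""
    times = traj.times if times is None else times
    rows = []
    for t in times:
        for sp in ("Na", "K", "Cl"):
            rows.append((t, "root_content_per_fw", "", sp,
                         root_ion_content_per_fw(traj, t, sp), "mol/kgFW"))
            rows.append((t, "flux_to_shoot", "", sp,
                         flux_to_shoot(traj, t, sp), "mol/s"))
        rows.append((t, "water_flux_to_shoot", "", "",
                     water_flux_to_shoot(traj, t), "m3/s"))
        for zone in ("apex", "mature"):
            rows.append((t, "mean_cytosolic_Na", zone, "Na",
                         mean_cytosolic_concentration(traj, t, zone, "Na"), "mol/m3"))
        rows.append((t, "antiporter_xylem_loading", "", "Na",
                     antiporter_xylem_loading(traj, t), "mol/s"))
        layer = traj.model.geometry.n_axial - 1
        rows.append((t, "epidermal_membrane_potential", "", "",
                     epidermal_membrane_potential(traj, t, layer), "V"))
    return pd.DataFrame(
        rows, columns=["time_s", "observable", "zone", "species", "value", "units"]
    )
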