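"""Two-stage parameter estimation against an experimental target table.

The fit exploits a structural separation: transport in the outer root
tissues influences *all* observables (root contents, epidermal potentials),
while stelar transport influences only the xylem concentrations and the
fluxes to the shoot.  Stage "outer" therefore fits the outer-tissue
parameters against root contents and epidermal potentials; stage "stele"
freezes those values and fits the stelar parameters against xylem
concentrations and the Na+ flux to the shoot.

The objective is weighted relative least squares, residual_i =
sqrt(w_i) * (model_i - target_i) / |target_i|, since targets span several
orders of magnitude across heterogeneous units.  Parameters are fitted in
log10 space (all are positive rate-like quantities) with bounded trust
region least squares and seeded Latin-hypercube multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .assembly import RootModel
from .config import RunConfig
from .parameters import BoundaryConditions, ModelParams, TransporterDistribution
from .simulate import Protocol, run_protocol, solve_presalt_steady_state
from .synthetic_data import MEDIA_PRESETS, OBSERVABLES

#: default free parameters and log10 bounds per stage
STAGE_FREE_PARAMS = {
    "outer": {
        "k_ap_outer": (1e-9, 1e-5),
        "P_nscc": (1e-10, 1e-7),
    },
    "stele": {
        "k_ap_stele": (1e-9, 1e-5),
        "P_hkt": (1e-9, 1e-7),
    },
}

TARGET_COLUMNS = [
    "observable", "genotype", "medium", "NaCl", "KCl", "Ca", "pH",
    "time_s", "value", "units", "weight", "stage",
]


class TargetTableError(ValueError):
    pass


def validate_targets(targets: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TARGET_COLUMNS if c not in targets.columns]
    if missing:
        raise TargetTableError(f"target table missing columns: {missing}")
    if (targets["weight"] <= 0).any():
        raise TargetTableError("target weights must be > 0")
    unknown = set(targets["observable"]) - set(OBSERVABLES)
    if unknown:
        raise TargetTableError(f"unknown observables: {sorted(unknown)}")
    return targets


@dataclass
class FitResult:
    stage: str
    parameters: dict
    bounds: dict
    objective: float
    residuals: pd.DataFrame
    n_starts: int
    starts: list = field(default_factory=list)  # per-start diagnostics
    fim_condition: float = np.nan
    identifiable: dict = field(default_factory=dict)
    success: bool = True

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "parameters": self.parameters,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "objective": self.objective,
            "n_starts": self.n_starts,
            "starts": self.starts,
            "fim_condition": None if np.isnan(self.fim_condition) else self.fim_condition,
            "identifiable": self.identifiable,
            "success": self.success,
        }


# ---------------------------------------------------------------------------
# forward prediction


def _apply_params(base: ModelParams, overrides: dict) -> ModelParams:
    bad = [k for k in overrides if not hasattr(base, k)]
    if bad:
        raise TargetTableError(f"unknown parameters: {bad}")
    return dc_replace(base, **overrides)


def predict_targets(
    config: RunConfig,
    params: ModelParams,
    targets: pd.DataFrame,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    warm: dict | None = None,
) -> np.ndarray:
    """Model predictions aligned with the target-table rows.

    Each distinct (medium, genotype, time) condition is simulated once from
    its own pre-salt steady state.  ``warm`` (a mutable dict owned by the
    caller) carries the previous steady state per condition as the next
    call's starting guess — the steady state is still re-solved to the same
    tolerance at every parameter value, just from a closer start.
    """
    geometry = config.build_geometry()
    graph = config.build_graph(geometry)
    preds = np.full(len(targets), np.nan)
    groups = targets.groupby(["medium", "genotype", "time_s"], sort=True)
    for (medium, genotype, time_s), idx in groups.groups.items():
        med = MEDIA_PRESETS[medium]
        salt_bc = BoundaryConditions(**med)
        pre_bc = BoundaryConditions(
            NaCl=min(0.5, salt_bc.NaCl), KCl=salt_bc.KCl,
            Ca=salt_bc.Ca, pH=salt_bc.pH,
        )
        dist = (TransporterDistribution.sos1_mutant(params)
                if genotype == "sos1"
                else TransporterDistribution.wild_type(params))
        model = RootModel(geometry, graph, params, dist, pre_bc)
        wkey = (medium, genotype)
        y_guess = warm.get(wkey) if warm is not None else None
        y0 = solve_presalt_steady_state(model, pre_bc, rtol=rtol, atol=atol,
                                        y0=y_guess)
        if warm is not None:
            warm[wkey] = y0
        protocol = Protocol(pre_salt=pre_bc, salt=salt_bc, salt_onset=0.0,
                            duration=float(time_s), output_times=[0.0, float(time_s)])
        traj = run_protocol(model, y0, protocol, rtol=rtol, atol=atol)
        for i in idx:
            fn, _, _ = OBSERVABLES[targets.at[i, "observable"]]
            preds[targets.index.get_loc(i)] = fn(traj, float(time_s))
    return preds


def residual_vector(preds: np.ndarray, targets: pd.DataFrame) -> np.ndarray:
    scale = np.abs(targets["value"].to_numpy())
    scale = np.where(scale > 0, scale, 1.0)
    w = np.sqrt(targets["weight"].to_numpy(dtype=float))
    return w * (preds - targets["value"].to_numpy()) / scale


# ---------------------------------------------------------------------------
# sensitivity screening


def sensitivity_screen(
    config: RunConfig,
    targets: pd.DataFrame,
    candidate_params: list[str],
    perturbation: float = 0.2,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Rank candidate parameters by normalized target sensitivity.

    Central differences in log-parameter space: s_ij =
    d log|pred_j| / d log p_i, evaluated at the config's parameter values.
    Parameters whose perturbed simulations fail are flagged, not dropped.
    """
    validate_targets(targets)
    base = config.build_params()
    rows = []
    for name in candidate_params:
        p0 = getattr(base, name)
        if p0 == 0:
            rows.append({"parameter": name, "max_abs_sensitivity": 0.0,
                         "mean_abs_sensitivity": 0.0, "status": "zero-valued"})
            continue
        try:
            hi = predict_targets(config, _apply_params(base, {name: p0 * (1 + perturbation)}),
                                 targets, rtol, atol)
            lo = predict_targets(config, _apply_params(base, {name: p0 / (1 + perturbation)}),
                                 targets, rtol, atol)
        except Exception as exc:
            rows.append({"parameter": name, "max_abs_sensitivity": np.nan,
                         "mean_abs_sensitivity": np.nan,
                         "status": f"failed: {type(exc).__name__}"})
            continue
        denom = 2.0 * np.log(1 + perturbation)
        ref = np.abs(targets["value"].to_numpy())
        ref = np.where(ref > 0, ref, 1.0)
        s = (hi - lo) / (ref * denom)
        rows.append({"parameter": name,
                     "max_abs_sensitivity": float(np.max(np.abs(s))),
                     "mean_abs_sensitivity": float(np.mean(np.abs(s))),
                     "status": "ok"})
    out = pd.DataFrame(rows).sort_values(
        ["max_abs_sensitivity", "parameter"], ascending=[False, True],
        na_position="last",
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# staged fitting


def fit_stage(
    stage: str,
    config: RunConfig,
    targets: pd.DataFrame,
    free: dict | None = None,
    fixed: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    xtol: float = 1e-8,
    warm: dict | None = None,
) -> FitResult:
    """Bounded weighted relative least squares for one stage.

    ``free`` maps parameter name -> (lower, upper) bounds; defaults to the
    stage's standard free set.  ``fixed`` overrides base parameter values
    (used to freeze the outer-stage result during the stele stage).
    Multi-start: seeded Latin-hypercube start points in log10 space, best
    result reported, all starts logged.
    """
    if stage not in STAGE_FREE_PARAMS:
        raise ValueError(f"unknown stage {stage!r}")
    if stage == "stele" and not fixed:
        raise ValueError(
            "stele stage requires the completed outer-stage parameters "
            "(pass them via `fixed`); run the outer stage first"
        )
    validate_targets(targets)
    stage_targets = targets[targets["stage"] == stage].reset_index(drop=True)
    if stage_targets.empty:
        raise TargetTableError(f"no targets for stage {stage!r}")
    free = dict(free if free is not None else STAGE_FREE_PARAMS[stage])
    fixed = dict(fixed or {})
    base = _apply_params(config.build_params(), fixed)

    if not free:
        preds = predict_targets(config, base, stage_targets, rtol, atol)
        r = residual_vector(preds, stage_targets)
        res_df = stage_targets.assign(prediction=preds, residual=r)
        return FitResult(stage=stage, parameters={}, bounds={},
                         objective=float(np.sum(r**2)), residuals=res_df,
                         n_starts=0)

    names = sorted(free)
    lo = np.log10([free[n][0] for n in names])
    hi = np.log10([free[n][1] for n in names])
    warm = warm if warm is not None else {}

    def resid(x):
        overrides = {n: 10.0 ** xi for n, xi in zip(names, x)}
        preds = predict_targets(config, _apply_params(base, overrides),
                                stage_targets, rtol, atol, warm=warm)
        return residual_vector(preds, stage_targets)

    # seeded Latin-hypercube multi-start (first start at the bound centre)
    centre = (lo + hi) / 2.0
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts = qmc.scale(sampler.random(n_starts - 1), lo, hi)
        x_starts = np.vstack([centre, starts])
    else:
        x_starts = np.array([centre])

    best = None
    log = []
    for k, x0 in enumerate(x_starts):
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=xtol, ftol=xtol, gtol=None,
                                diff_step=0.05)
            entry = {"start": k, "x0": list(x0), "cost": float(2 * sol.cost),
                     "x": list(sol.x), "status": int(sol.status)}
            if best is None or 2 * sol.cost < best["cost"]:
                best = {"cost": float(2 * sol.cost), "sol": sol}
        except Exception as exc:
            entry = {"start": k, "x0": list(x0), "cost": np.inf,
                     "status": f"failed: {type(exc).__name__}: {exc}"}
        log.append(entry)
    if best is None:
        raise RuntimeError(f"all {len(x_starts)} starts failed: {log}")

    sol = best["sol"]
    fitted = {n: float(10.0 ** xi) for n, xi in zip(names, sol.x)}
    preds = predict_targets(config, _apply_params(base, fitted),
                            stage_targets, rtol, atol)
    r = residual_vector(preds, stage_targets)
    res_df = stage_targets.assign(prediction=preds, residual=r)

    # local identifiability from the FIM in log-parameter space
    J = sol.jac
    fim = J.T @ J
    try:
        cond = float(np.linalg.cond(fim))
        ev = np.linalg.eigvalsh(fim)
        ident = {n: bool(ev.min() > 1e-8 * max(ev.max(), 1e-30)) for n in names}
    except np.linalg.LinAlgError:
        cond, ident = np.nan, {n: False for n in names}

    return FitResult(
        stage=stage, parameters=fitted, bounds=free,
        objective=float(np.sum(r**2)), residuals=res_df,
        n_starts=len(x_starts), starts=log, fim_condition=cond,
        identifiable=ident,
    )


def two_stage_fit(
    config: RunConfig,
    targets: pd.DataFrame,
    outer_free: dict | None = None,
    stele_free: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    xtol: float = 1e-8,
    warm: dict | None = None,
) -> tuple[FitResult, FitResult]:
    """Outer stage (root contents + epidermal potentials), then stele stage
    (xylem concentrations + Na+ flux to shoot) with the outer parameters
    frozen at their fitted values."""
    warm = warm if warm is not None else {}
    outer = fit_stage("outer", config, targets, free=outer_free,
                      n_starts=n_starts, seed=seed, rtol=rtol, atol=atol,
                      xtol=xtol, warm=warm)
    stele = fit_stage("stele", config, targets, free=stele_free,
                      fixed=outer.parameters, n_starts=n_starts,
                      seed=seed + 1, rtol=rtol, atol=atol, xtol=xtol,
                      warm=warm)
    return outer, stele
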