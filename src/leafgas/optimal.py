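"""Numerical Cowan-Farquhar stomatal optimality.

Stomata are assumed to maximise carbon gain minus the cost of the water
spent: the operating Ci is the one maximising ``An - lambda E``, where
``lambda`` (mol C mol-1 H2O) is the marginal cost of water. An follows
the FvCB demand function, gs comes from rearranging the supply function
(gs = 1.6 An / (Ca - Ci)) and E assumes perfect coupling, E = gs D / Pa
(mol m-2 s-1). The objective is evaluated in umol m-2 s-1, so the water
cost term is ``lambda * E * 1e6``.

The search is a dense grid scan followed by bounded local refinement
around the best grid point; concavity of the objective is never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import constants as k
from .coupled import (EnvironmentalDrivers, boundary_layer_conductance,
                      penman_monteith)
from .fvcb import BiochemParams, DomainError, as_scalar, demand_at_ci

__all__ = [
    "OptimalityParams",
    "OptimumResult",
    "objective",
    "find_optimum",
    "gs_d_response",
]


@dataclass(frozen=True)
class OptimalityParams:
    """Settings for the optimal-Ci search."""

    lam: float = 0.002          # marginal cost of water (mol C mol-1 H2O)
    search_lower: float | None = None   # umol mol-1; default 0.01 Ca
    search_upper: float | None = None   # umol mol-1; default 0.999 Ca
    grid_n: int = 500
    refine_xatol: float = 1e-4  # umol mol-1
    energy_balance: bool = False

    def __post_init__(self):
        if self.lam < 0:
            raise DomainError("lam must be >= 0")
        if self.grid_n < 3:
            raise DomainError("grid_n must be >= 3")

    def bounds(self, ca: float) -> tuple[float, float]:
        lo = 0.01 * ca if self.search_lower is None else self.search_lower
        hi = 0.999 * ca if self.search_upper is None else self.search_upper
        if not (lo < hi <= ca):
            raise DomainError("need search_lower < search_upper <= ca")
        return lo, hi


@dataclass
class OptimumResult:
    """Optimal stomatal behaviour at one set of drivers."""

    ci_opt: float
    an: float
    gs: float
    e: float                # mmol m-2 s-1
    objective: float        # umol m-2 s-1 net of the water cost
    interior_optimum: bool
    tleaf: float
    d: float


def objective(ci, env: EnvironmentalDrivers, params: BiochemParams,
              lam: float):
    """The quantity An - lambda E at intercellular CO2 ``ci``.

    Vectorised over ``ci``; requires ci < ca so the rearranged supply
    function gives a finite gs.
    """
    scalar = np.ndim(ci) == 0
    ci = np.asarray(ci, dtype=float)
    if np.any(ci >= env.ca):
        raise DomainError("ci must be < ca")
    an = np.asarray(demand_at_ci(ci, params, tleaf=env.tleaf,
                                 par=env.par).an)
    gs = k.GS_CO2_RATIO * an / (env.ca - ci)
    e_mol = gs * env.vpd / env.pa
    out = an - lam * e_mol * 1e6
    return as_scalar(out) if scalar else out


def _eb_point(ci, env, params, lam, max_iter=50, tol=0.01):
    """Objective and state at one ci with the leaf energy balance closed."""
    tair = env.air_temperature
    gbh, gbw = boundary_layer_conductance(env.wind, env.leaf_width)
    tk = tair + 273.15
    to_ms = k.GAS_CONSTANT * tk / (env.pa * 1000.0)
    rho_cp = (env.pa * 1000.0 * k.MOLAR_MASS_AIR
              / (k.GAS_CONSTANT * tk)) * k.CP_AIR
    lam_mol = k.latent_heat_vaporisation(tair) * k.MOLAR_MASS_H2O
    tleaf, converged = tair, False
    an = gs = e_mmol = 0.0
    for _ in range(max_iter):
        an = as_scalar((demand_at_ci(ci, params, tleaf=tleaf,
                                           par=env.par).an))
        gs = max(k.GS_CO2_RATIO * an / (env.ca - ci), 0.0)
        e_mmol = penman_monteith(env.rnet, env.vpd, tair, gs, gbw, pa=env.pa)
        le = e_mmol / 1000.0 * lam_mol
        step = tair + (env.rnet - le) / (rho_cp * gbh * to_ms) - tleaf
        tleaf += 0.7 * step
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        return None
    obj = an - lam * e_mmol / 1000.0 * 1e6
    return obj, an, gs, e_mmol, tleaf


def find_optimum(env: EnvironmentalDrivers, params: BiochemParams,
                 opts: OptimalityParams | None = None) -> OptimumResult:
    """Locate the Ci maximising An - lambda E.

    Coarse grid scan over the search interval, then bounded parabolic
    refinement between the neighbours of the best grid point. The result
    is flagged non-interior when the maximum sits on a search bound (as
    happens for lambda = 0, where water is free and the objective is
    monotone in Ci).
    """
    opts = opts or OptimalityParams()
    lo, hi = opts.bounds(env.ca)
    grid = np.linspace(lo, hi, opts.grid_n)

    if opts.energy_balance:
        vals = np.full(opts.grid_n, -np.inf)
        states = {}
        for i, ci in enumerate(grid):
            pt = _eb_point(ci, env, params, opts.lam)
            if pt is not None:
                vals[i] = pt[0]
                states[i] = pt
        if not np.any(np.isfinite(vals)):
            raise DomainError("objective non-finite across the whole grid")
        i = int(np.argmax(vals))

        def neg(ci):
            pt = _eb_point(as_scalar(ci), env, params, opts.lam)
            return np.inf if pt is None else -pt[0]
    else:
        vals = objective(grid, env, params, opts.lam)
        if not np.any(np.isfinite(vals)):
            raise DomainError("objective non-finite across the whole grid")
        i = int(np.argmax(vals))

        def neg(ci):
            return -objective(as_scalar(ci), env, params, opts.lam)

    interior = 0 < i < opts.grid_n - 1
    if interior:
        res = optimize.minimize_scalar(
            neg, bounds=(grid[i - 1], grid[i + 1]), method="bounded",
            options={"xatol": opts.refine_xatol})
        ci_opt = as_scalar(res.x) if -res.fun >= vals[i] else float(grid[i])
    else:
        ci_opt = float(grid[i])

    if opts.energy_balance:
        pt = _eb_point(ci_opt, env, params, opts.lam) or states[i]
        obj, an, gs, e_mmol, tleaf = pt
    else:
        obj = objective(ci_opt, env, params, opts.lam)
        an = as_scalar((demand_at_ci(ci_opt, params, tleaf=env.tleaf,
                                           par=env.par).an))
        gs = max(k.GS_CO2_RATIO * an / (env.ca - ci_opt), 0.0)
        e_mmol = gs * env.vpd / env.pa * 1000.0
        tleaf = env.tleaf
    return OptimumResult(ci_opt=ci_opt, an=an, gs=float(gs),
                         e=float(e_mmol), objective=float(obj),
                         interior_optimum=interior, tleaf=float(tleaf),
                         d=env.vpd)


def gs_d_response(d_values, env: EnvironmentalDrivers,
                  params: BiochemParams,
                  opts: OptimalityParams | None = None) -> pd.DataFrame:
    """Optimal (gs, An, Ci) across a sweep of vapour pressure deficits.

    One row per D; rows where no interior optimum exists are flagged in
    the ``interior_optimum`` column, never dropped.
    """
    from dataclasses import replace
    opts = opts or OptimalityParams()
    rows = []
    for d in np.asarray(d_values, dtype=float):
        if d <= 0:
            raise DomainError("d values must be > 0")
        try:
            r = find_optimum(replace(env, vpd=float(d)), params, opts)
            rows.append({"d": d, "ci_opt": r.ci_opt, "gs_opt": r.gs,
                         "an_opt": r.an, "e_opt": r.e,
                         "objective": r.objective,
                         "interior_optimum": r.interior_optimum,
                         "ok": True})
        except DomainError:
            rows.append({"d": d, "ci_opt": np.nan, "gs_opt": np.nan,
                         "an_opt": np.nan, "e_opt": np.nan,
                         "objective": np.nan, "interior_optimum": False,
                         "ok": False})
    return pd.DataFrame(rows)
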