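"""Coupled leaf gas exchange: supply = demand, stomatal model, energy balance.

The steady-state operating point of a leaf is the intersection of the
biochemical demand function An(Ci) with the diffusion supply function
``An = (gs/1.6)(Ca - Ci)``. Three modes are provided:

- Ci given: evaluate the demand function, back-compute gs from supply.
- gs given: solve the intersection for Ci.
- fully coupled: gs itself follows a Ball-Berry-type model of An, so the
  operating point solves demand, supply and the gs model simultaneously.

``photosyn_eb`` additionally closes the leaf energy balance: transpiration
from the Penman-Monteith combination equation (boundary-layer aware) and
leaf temperature from Rnet = lambda E + H.

In the non-energy-balance modes, transpiration assumes perfect coupling
to the atmosphere: E = gs D / Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from . import constants as k
from .fvcb import BiochemParams, DomainError, as_scalar, demand_at_ci
from .gsmodels import gs_predict
from .met import esat

__all__ = [
    "EnvironmentalDrivers",
    "CoupledSolution",
    "NoSolutionError",
    "supply_an",
    "photosyn_given_ci",
    "photosyn_given_gs",
    "photosyn_coupled",
    "penman_monteith",
    "boundary_layer_conductance",
    "photosyn_eb",
]

VPD_FLOOR = 0.05  # kPa; 1/sqrt(D) in the optimality gs model diverges at 0


class NoSolutionError(RuntimeError):
    """No steady-state operating point exists for the given drivers."""


@dataclass(frozen=True)
class EnvironmentalDrivers:
    """Environmental drivers of leaf gas exchange."""

    par: float = 1500.0       # umol m-2 s-1
    tleaf: float = 25.0       # C (leaf; used directly except in EB mode)
    tair: float | None = None  # C (air; defaults to tleaf)
    vpd: float = 1.5          # kPa
    ca: float = 400.0         # umol mol-1
    pa: float = k.PRESSURE_KPA  # kPa
    wind: float = 2.0         # m s-1 (EB mode)
    leaf_width: float = 0.02  # m (EB mode)
    rnet: float = 300.0       # W m-2 (EB mode)

    def __post_init__(self):
        if self.ca <= 0:
            raise DomainError("ca must be > 0")
        if self.vpd < 0:
            raise DomainError("vpd must be >= 0")
        if self.pa <= 0:
            raise DomainError("pa must be > 0")

    @property
    def air_temperature(self) -> float:
        return self.tleaf if self.tair is None else self.tair


@dataclass
class CoupledSolution:
    """Simultaneous leaf gas-exchange state."""

    an: float        # net assimilation (umol m-2 s-1)
    gs: float        # stomatal conductance to H2O (mol m-2 s-1)
    e: float         # transpiration (mmol m-2 s-1)
    ci: float        # intercellular CO2 (umol mol-1)
    cc: float        # chloroplastic CO2 (umol mol-1)
    ac: float        # gross Rubisco-limited rate
    aj: float        # gross RuBP-regeneration-limited rate
    tleaf: float     # C
    ite: float       # An/E (umol mmol-1); nan when E = 0
    mode: str        # ci_given | gs_given | coupled | coupled_eb
    converged: bool = True
    closure: float = 0.0  # energy-balance residual (W m-2), EB mode only


def supply_an(gs, ca, ci):
    """Diffusion supply of CO2: An = (gs/1.6)(Ca - Ci), umol m-2 s-1."""
    gs = np.asarray(gs, dtype=float)
    if np.any(gs < 0):
        raise DomainError("gs must be >= 0")
    out = gs / k.GS_CO2_RATIO * (np.asarray(ca, float) - np.asarray(ci, float))
    return out if np.ndim(out) else float(out)


def _solution_from_ci(env, params, ci, gs, mode, tleaf=None,
                      converged=True, e_mmol=None, closure=0.0):
    tleaf = env.tleaf if tleaf is None else tleaf
    d = demand_at_ci(ci, params, tleaf=tleaf, par=env.par)
    an = as_scalar((d.an))
    if e_mmol is None:
        e_mmol = gs * env.vpd / env.pa * 1000.0  # perfect coupling
    ite = an / e_mmol if e_mmol > 0 else float("nan")
    return CoupledSolution(an=an, gs=float(gs), e=float(e_mmol),
                           ci=float(ci), cc=as_scalar((d.cc)),
                           ac=as_scalar((d.ac)),
                           aj=as_scalar((d.aj)), tleaf=float(tleaf),
                           ite=ite, mode=mode, converged=converged,
                           closure=closure)


def photosyn_given_ci(env: EnvironmentalDrivers, params: BiochemParams,
                      ci: float) -> CoupledSolution:
    """Leaf gas exchange with Ci prescribed (the pure demand curve).

    gs is back-computed from the supply function and is therefore only
    meaningful for ci < ca with an >= 0.
    """
    d = demand_at_ci(ci, params, tleaf=env.tleaf, par=env.par)
    an = as_scalar((d.an))
    gs = k.GS_CO2_RATIO * an / (env.ca - ci) if ci < env.ca else 0.0
    gs = max(gs, 0.0)
    return _solution_from_ci(env, params, ci, gs, "ci_given")


def photosyn_given_gs(env: EnvironmentalDrivers, params: BiochemParams,
                      gs: float, tleaf=None) -> CoupledSolution:
    """Solve supply = demand for Ci at a prescribed stomatal conductance."""
    if gs < 0:
        raise DomainError("gs must be >= 0")
    tleaf = env.tleaf if tleaf is None else tleaf

    def h(ci):
        an = as_scalar((demand_at_ci(ci, params, tleaf=tleaf,
                                           par=env.par).an))
        return an - supply_an(gs, env.ca, ci)

    lo, hi = 1e-6, 10.0 * env.ca  # ci may exceed ca when an < 0
    if gs == 0.0:
        # supply is identically zero: root of the demand function itself
        if h(lo) * h(hi) > 0:
            raise NoSolutionError("demand has no zero: no steady state "
                                  "with gs = 0")
    ci = optimize.brentq(h, lo, hi, xtol=1e-12, rtol=1e-14)
    return _solution_from_ci(env, params, ci, gs, "gs_given", tleaf=tleaf)


def photosyn_coupled(env: EnvironmentalDrivers, params: BiochemParams,
                     variant="medlyn_opti", g0=0.0, g1=4.0, d0=1.5,
                     tleaf=None, _mode="coupled") -> CoupledSolution:
    """Solve the fully coupled model: demand, supply and the gs model.

    The single unknown is Ci; gs follows the chosen Ball-Berry variant
    evaluated at the demand An(Ci), floored at g0 (and 0). When the demand
    is negative everywhere (e.g. PAR = 0) the stomatal model is off its
    domain; the documented night-time rule applies: gs = g0 and the
    operating point solves supply = demand at that conductance, which
    fails (flagged) when g0 = 0.
    """
    tleaf = env.tleaf if tleaf is None else tleaf
    d = env.vpd
    if d < VPD_FLOOR:
        warnings.warn(f"vpd clamped at the {VPD_FLOOR} kPa floor",
                      stacklevel=2)
        d = VPD_FLOOR
    rh = None
    if variant == "ball_berry_rh":
        rh = float(np.clip(100.0 * (1.0 - d / esat(tleaf)), 0.0, 100.0))

    def gs_of(an):
        gs = gs_predict(variant, g0, g1, an, env.ca, d=d, rh=rh, d0=d0)
        return max(float(gs), g0, 0.0)

    def h(ci):
        an = as_scalar((demand_at_ci(ci, params, tleaf=tleaf,
                                           par=env.par).an))
        return an - supply_an(gs_of(an), env.ca, ci)

    lo, hi = 1e-6, env.ca * (1.0 - 1e-12)
    flo, fhi = h(lo), h(hi)
    if flo * fhi > 0:
        # demand likely negative throughout [0, ca]: night-time rule
        try:
            sol = photosyn_given_gs(replace(env, vpd=d), params, max(g0, 0.0),
                                    tleaf=tleaf)
        except NoSolutionError as err:
            raise NoSolutionError(
                "coupled model has no operating point (negative demand "
                "and g0 = 0)") from err
        return replace(sol, mode=_mode)
    ci = optimize.brentq(h, lo, hi, xtol=1e-12, rtol=1e-14)
    an = as_scalar((demand_at_ci(ci, params, tleaf=tleaf,
                                       par=env.par).an))
    return _solution_from_ci(replace(env, vpd=d), params, ci, gs_of(an),
                             _mode, tleaf=tleaf)


def _esat_slope(tair_c):
    """Slope of saturation vapour pressure (Pa K-1) at tair (C)."""
    dt = 0.1
    return (esat(tair_c + dt) - esat(tair_c - dt)) / (2 * dt) * 1000.0


def penman_monteith(rnet, d, tair, gs, gbl, pa=k.PRESSURE_KPA):
    """Transpiration (mmol m-2 s-1) from the Penman-Monteith equation.

    Combination form for a leaf with boundary-layer conductance ``gbl``
    and stomatal conductance ``gs`` (both mol m-2 s-1, H2O basis):
    ``lambda E = (s Rnet + rho cp D ga) / (s + gamma (1 + ga/gv))``.
    In the well-coupled limit (gbl -> inf) with no radiative term this
    reduces to the imposed transpiration E = gs D / Pa.
    """
    if gbl <= 0:
        raise DomainError("gbl must be > 0")
    if gs < 0:
        raise DomainError("gs must be >= 0")
    if gs == 0.0:
        return 0.0
    tk = tair + 273.15
    p_pa = pa * 1000.0
    to_ms = k.GAS_CONSTANT * tk / p_pa        # mol m-2 s-1 -> m s-1
    ga, gv = gbl * to_ms, gs * to_ms
    s = _esat_slope(tair)                     # Pa K-1
    lam = k.latent_heat_vaporisation(tair)    # J kg-1
    rho = p_pa * k.MOLAR_MASS_AIR / (k.GAS_CONSTANT * tk)  # kg m-3
    gamma = k.CP_AIR * p_pa / (
        lam * k.MOLAR_MASS_H2O / k.MOLAR_MASS_AIR)         # Pa K-1
    le = (s * rnet + rho * k.CP_AIR * d * 1000.0 * ga) / (
        s + gamma * (1.0 + ga / gv))                       # W m-2
    e_mol = max(le, 0.0) / (lam * k.MOLAR_MASS_H2O)
    return e_mol * 1000.0


def boundary_layer_conductance(wind, leaf_width):
    """Forced-convection flat-plate boundary-layer conductances.

    Returns (heat, H2O) conductances in mol m-2 s-1, one leaf side:
    gbH = 0.135 sqrt(u/w), gbW = 0.147 sqrt(u/w).
    """
    if wind <= 0 or leaf_width <= 0:
        raise DomainError("wind and leaf_width must be > 0")
    root = np.sqrt(wind / leaf_width)
    return 0.135 * root, 0.147 * root


def photosyn_eb(env: EnvironmentalDrivers, params: BiochemParams,
                variant="medlyn_opti", g0=0.0, g1=4.0, d0=1.5,
                max_iter=50, tol=0.01) -> CoupledSolution:
    """Coupled gas exchange with leaf temperature from the energy balance.

    Iterates: gas exchange at the current Tleaf -> Penman-Monteith E ->
    sensible heat from the residual Rnet - lambda E -> new Tleaf, until
    successive Tleaf values change by less than ``tol`` (C). Air-based D
    drives the stomatal model. Non-convergence is flagged on the returned
    solution rather than raised.
    """
    tair = env.air_temperature
    gbh, gbw = boundary_layer_conductance(env.wind, env.leaf_width)
    tk = tair + 273.15
    p_pa = env.pa * 1000.0
    to_ms = k.GAS_CONSTANT * tk / p_pa
    rho_cp = p_pa * k.MOLAR_MASS_AIR / (k.GAS_CONSTANT * tk) * k.CP_AIR
    lam_mol = k.latent_heat_vaporisation(tair) * k.MOLAR_MASS_H2O  # J mol-1

    tleaf = tair
    converged = False
    sol = None
    e_mmol = 0.0
    for _ in range(max_iter):
        sol = photosyn_coupled(env, params, variant=variant, g0=g0, g1=g1,
                               d0=d0, tleaf=tleaf, _mode="coupled_eb")
        e_mmol = penman_monteith(env.rnet, env.vpd, tair, sol.gs, gbw,
                                 pa=env.pa)
        le = e_mmol / 1000.0 * lam_mol                    # W m-2
        tleaf_new = tair + (env.rnet - le) / (rho_cp * gbh * to_ms)
        step = tleaf_new - tleaf
        tleaf += 0.7 * step
        if abs(step) < tol:
            converged = True
            break
    h_sens = rho_cp * gbh * to_ms * (tleaf - tair)
    le = e_mmol / 1000.0 * lam_mol
    closure = env.rnet - le - h_sens
    if not converged:
        warnings.warn("energy balance did not converge in "
                      f"{max_iter} iterations", stacklevel=2)
    ite = sol.an / e_mmol if e_mmol > 0 else float("nan")
    return replace(sol, tleaf=float(tleaf), e=float(e_mmol), ite=ite,
                   converged=converged, closure=float(closure))
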