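"""The biochemical demand side of leaf photosynthesis (C3).

Implements the Farquhar-von Caemmerer-Berry (FvCB) model: net CO2
assimilation as the (hyperbolic) minimum of the Rubisco-limited and
RuBP-regeneration-limited gross rates, each of the form
``k1 (Cc - GammaStar) / (k2 + Cc)``, with standard Arrhenius-type
temperature responses for all kinetic parameters.

When a finite mesophyll conductance ``gm`` is supplied, chloroplastic CO2
is ``Cc = Ci - An/gm`` and each limitation is solved analytically as a
quadratic in An (Ethier-Livingston style), so no iteration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as k

__all__ = [
    "TemperatureResponse",
    "BiochemParams",
    "DemandResult",
    "arrhenius",
    "electron_transport",
    "gross_limited_rate",
    "hyperbolic_min",
    "demand_at_ci",
]


class DomainError(ValueError):
    """Raised when an input is outside the physically meaningful range."""


def as_scalar(x) -> float:
    """First element of an array-like as a float (scalar convenience)."""
    return float(np.asarray(x).ravel()[0])


@dataclass(frozen=True)
class TemperatureResponse:
    """Arrhenius-type temperature response of a rate or Michaelis constant.

    With ``deactivation_energy == 0`` this is a plain Arrhenius response;
    otherwise the peaked (deactivated) form with an entropy term is used.
    Evaluating at the 25 C reference temperature returns ``reference_value``
    exactly in either form.

    Parameters
    ----------
    reference_value : float
        Value at 25 C (rate or concentration; units of the quantity).
    activation_energy : float
        Ea, J mol-1.
    deactivation_energy : float
        Hd, J mol-1; 0 selects the plain Arrhenius form.
    entropy_term : float
        dS, J mol-1 K-1 (only used in the peaked form).
    """

    reference_value: float
    activation_energy: float
    deactivation_energy: float = 0.0
    entropy_term: float = 0.0
    reference_temperature: float = k.TREF_C

    def __post_init__(self):
        if self.reference_value <= 0:
            raise DomainError("reference_value must be positive")
        if self.reference_temperature != k.TREF_C:
            raise DomainError("reference_temperature is fixed at 25 C")

    def at(self, tleaf):
        return arrhenius(self, tleaf)


def arrhenius(tr: TemperatureResponse, tleaf):
    """Evaluate a temperature response at leaf temperature (C).

    Plain Arrhenius when ``deactivation_energy == 0``; the peaked
    (deactivated) form otherwise. Continuous in ``tleaf``; valid for
    tleaf in [-10, 60] C.
    """
    tleaf = np.asarray(tleaf, dtype=float)
    if np.any(tleaf < -10.0) or np.any(tleaf > 60.0):
        raise DomainError("tleaf outside the supported range [-10, 60] C")
    tk = tleaf + 273.15
    r = k.GAS_CONSTANT
    tref = k.TREF_K
    arrh = np.exp(tr.activation_energy * (tk - tref) / (tref * r * tk))
    if tr.deactivation_energy == 0.0:
        out = tr.reference_value * arrh
    else:
        hd, sv = tr.deactivation_energy, tr.entropy_term
        num = 1.0 + np.exp((tref * sv - hd) / (tref * r))
        den = 1.0 + np.exp((tk * sv - hd) / (tk * r))
        out = tr.reference_value * arrh * num / den
    return out if out.ndim else float(out)


def _tr(value, ea, hd=0.0, sv=0.0):
    return TemperatureResponse(value, ea, hd, sv)


@dataclass(frozen=True)
class BiochemParams:
    """FvCB parameter set: capacities at 25 C plus kinetic constants.

    ``gm`` is the mesophyll conductance (mol m-2 s-1); ``None`` means
    infinite (Ci is used as the driver of photosynthesis).
    """

    vcmax25: float = 50.0     # max Rubisco carboxylation rate (umol m-2 s-1)
    jmax25: float = 100.0     # max electron transport rate (umol m-2 s-1)
    rd25: float = 1.5         # dark respiration at 25 C (umol m-2 s-1)
    gm: float | None = None   # mesophyll conductance (mol m-2 s-1) or None
    kc25: float = k.KC25
    ko25: float = k.KO25
    gammastar25: float = k.GAMMASTAR25
    oi: float = k.OI          # O2 mole fraction (mmol mol-1)
    alpha: float = k.ALPHA_J
    theta_j: float = k.THETA_J
    theta_hmin: float = k.THETA_HMIN
    # temperature responses (activation/deactivation energies, entropy terms)
    ea_vcmax: float = k.EA_VCMAX
    hd_vcmax: float = k.HD_VCMAX
    sv_vcmax: float = k.SV_VCMAX
    ea_jmax: float = k.EA_JMAX
    hd_jmax: float = k.HD_JMAX
    sv_jmax: float = k.SV_JMAX
    ea_rd: float = k.EA_RD
    ea_kc: float = k.EA_KC
    ea_ko: float = k.EA_KO
    ea_gammastar: float = k.EA_GAMMASTAR

    def __post_init__(self):
        for name in ("vcmax25", "jmax25", "rd25", "kc25", "ko25",
                     "gammastar25", "oi"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (0.0 < self.theta_hmin <= 1.0):
            raise DomainError("theta_hmin must be in (0, 1]")
        if not (0.0 < self.theta_j <= 1.0):
            raise DomainError("theta_j must be in (0, 1]")
        if self.gm is not None and self.gm <= 0:
            raise DomainError("gm must be positive when finite")

    def with_(self, **kwargs) -> "BiochemParams":
        return replace(self, **kwargs)

    # Temperature-corrected parameter values at tleaf (C)
    def vcmax_at(self, tleaf):
        return arrhenius(_tr(self.vcmax25, self.ea_vcmax, self.hd_vcmax,
                             self.sv_vcmax), tleaf)

    def jmax_at(self, tleaf):
        return arrhenius(_tr(self.jmax25, self.ea_jmax, self.hd_jmax,
                             self.sv_jmax), tleaf)

    def rd_at(self, tleaf):
        if self.rd25 == 0:
            z = np.zeros_like(np.asarray(tleaf, dtype=float))
            return z if z.ndim else 0.0
        return arrhenius(_tr(self.rd25, self.ea_rd), tleaf)

    def kc_at(self, tleaf):
        return arrhenius(_tr(self.kc25, self.ea_kc), tleaf)

    def ko_at(self, tleaf):
        return arrhenius(_tr(self.ko25, self.ea_ko), tleaf)

    def gammastar_at(self, tleaf):
        return arrhenius(_tr(self.gammastar25, self.ea_gammastar), tleaf)

    def km_at(self, tleaf):
        """Effective Michaelis constant Km = Kc (1 + Oi/Ko), umol mol-1."""
        return self.kc_at(tleaf) * (1.0 + self.oi / self.ko_at(tleaf))


@dataclass
class DemandResult:
    """Full output of the demand function at one or more Ci values."""

    an: np.ndarray       # net assimilation (umol m-2 s-1)
    ac: np.ndarray       # gross Rubisco-limited rate
    aj: np.ndarray       # gross RuBP-regeneration-limited rate
    am: np.ndarray       # hyperbolic-minimum gross rate
    j: float             # electron transport rate at this PAR/Tleaf
    km: float            # Kc (1 + Oi/Ko) at tleaf (umol mol-1)
    gammastar: float     # CO2 compensation point without Rd at tleaf
    vcmax_t: float
    jmax_t: float
    rd_t: float
    cc: np.ndarray       # chloroplastic CO2 (umol mol-1)

    def squeeze(self) -> "DemandResult":
        """Collapse length-1 arrays to scalars (convenience for scalar Ci)."""
        def sq(x):
            x = np.asarray(x)
            return float(x) if x.size == 1 else x
        return DemandResult(**{f: sq(getattr(self, f))
                               for f in self.__dataclass_fields__})


def electron_transport(par, jmax_t, alpha=k.ALPHA_J, theta_j=k.THETA_J):
    """Electron transport rate J from the non-rectangular hyperbola.

    Smaller root of ``theta J^2 - (alpha Q + Jmax) J + alpha Q Jmax = 0``;
    saturates at ``jmax_t`` for high PAR and is 0 at PAR = 0.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise DomainError("par must be >= 0")
    aq = alpha * par
    b = aq + jmax_t
    disc = np.maximum(b * b - 4.0 * theta_j * aq * jmax_t, 0.0)
    j = (b - np.sqrt(disc)) / (2.0 * theta_j)
    return j if j.ndim else float(j)


def gross_limited_rate(cc, k1, k2, gammastar):
    """One FvCB limitation: ``k1 (cc - gammastar) / (k2 + cc)``.

    For the Rubisco limb k1 = Vcmax and k2 = Km; for the RuBP limb
    k1 = J/4 and k2 = 2 GammaStar.
    """
    cc = np.asarray(cc, dtype=float)
    out = k1 * (cc - gammastar) / (k2 + cc)
    return out if out.ndim else float(out)


def hyperbolic_min(ac, aj, theta_hmin=k.THETA_HMIN):
    """Smooth (hyperbolic) minimum of the two limitation rates.

    ``(ac+aj - sqrt((ac+aj)^2 - 4 theta ac aj)) / (2 theta)``; symmetric in
    its first two arguments and never above min(ac, aj). The discriminant is
    clamped at zero as a numerical guard.
    """
    if not (0.0 < theta_hmin <= 1.0):
        raise DomainError("theta_hmin must be in (0, 1]")
    ac = np.asarray(ac, dtype=float)
    aj = np.asarray(aj, dtype=float)
    s = ac + aj
    disc = np.maximum(s * s - 4.0 * theta_hmin * ac * aj, 0.0)
    am = (s - np.sqrt(disc)) / (2.0 * theta_hmin)
    return am if am.ndim else float(am)


def _net_rate_with_gm(ci, k1, k2, gammastar, rd, gm):
    """Net rate for one limitation with finite mesophyll conductance.

    Solves {An = k1 (Cc - GammaStar)/(k2 + Cc) - Rd, Cc = Ci - An/gm}
    as a quadratic in An and returns the physically valid (smaller) root,
    for which Cc <= Ci.
    """
    b = gm * (ci + k2) + k1 - rd
    c = gm * (k1 * (ci - gammastar) - rd * (ci + k2))
    disc = np.maximum(b * b - 4.0 * c, 0.0)
    return (b - np.sqrt(disc)) / 2.0


def limb_net_rate(ci, params: BiochemParams, tleaf=25.0,
                  par=k.PAR_SATURATING, limb="ac"):
    """Net assimilation from a single limitation ('ac' or 'aj') only.

    Used when the Rubisco/RuBP transition is imposed externally; supports
    finite mesophyll conductance through the same per-limb quadratic as
    :func:`demand_at_ci`.
    """
    ci = np.atleast_1d(np.asarray(ci, dtype=float))
    if np.any(ci < 0):
        raise DomainError("ci must be >= 0")
    rd_t = params.rd_at(tleaf)
    gammastar = params.gammastar_at(tleaf)
    if limb == "ac":
        k1, k2 = params.vcmax_at(tleaf), params.km_at(tleaf)
    elif limb == "aj":
        j = electron_transport(par, params.jmax_at(tleaf), params.alpha,
                               params.theta_j)
        k1, k2 = j / 4.0, 2.0 * gammastar
    else:
        raise ValueError("limb must be 'ac' or 'aj'")
    if params.gm is None:
        return gross_limited_rate(ci, k1, k2, gammastar) - rd_t
    return _net_rate_with_gm(ci, k1, k2, gammastar, rd_t, params.gm)


def demand_at_ci(ci, params: BiochemParams, tleaf=25.0,
                 par=k.PAR_SATURATING) -> DemandResult:
    """Evaluate the FvCB demand function at intercellular CO2 ``ci``.

    ``ci`` may be a scalar or array (umol mol-1). ``tleaf`` and ``par`` are
    scalars for a single evaluation condition. With ``params.gm`` set, the
    implicit Cc dependence is solved analytically per limitation before the
    hyperbolic minimum is taken.
    """
    ci = np.atleast_1d(np.asarray(ci, dtype=float))
    if np.any(ci < 0):
        raise DomainError("ci must be >= 0")

    vcmax_t = params.vcmax_at(tleaf)
    jmax_t = params.jmax_at(tleaf)
    rd_t = params.rd_at(tleaf)
    gammastar = params.gammastar_at(tleaf)
    km = params.km_at(tleaf)
    j = electron_transport(par, jmax_t, params.alpha, params.theta_j)

    if params.gm is None:
        cc = ci
        ac = gross_limited_rate(cc, vcmax_t, km, gammastar)
        aj = gross_limited_rate(cc, j / 4.0, 2.0 * gammastar, gammastar)
    else:
        gm = params.gm
        ac = _net_rate_with_gm(ci, vcmax_t, km, gammastar, rd_t, gm) + rd_t
        aj = _net_rate_with_gm(ci, j / 4.0, 2.0 * gammastar, gammastar,
                               rd_t, gm) + rd_t

    am = hyperbolic_min(ac, aj, params.theta_hmin)
    an = am - rd_t
    cc = ci if params.gm is None else ci - an / params.gm

    return DemandResult(an=an, ac=np.atleast_1d(ac), aj=np.atleast_1d(aj),
                        am=am, j=float(j), km=float(km),
                        gammastar=float(gammastar), vcmax_t=float(vcmax_t),
                        jmax_t=float(jmax_t), rd_t=float(rd_t),
                        cc=np.atleast_1d(cc))
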