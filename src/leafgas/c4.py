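"""C4 photosynthesis: dependence of An on intercellular CO2.

Enzyme-limited and light-limited rates of the von Caemmerer C4 model,
each obtained as the smaller root of a quadratic that couples mesophyll
PEP carboxylation with bundle-sheath Rubisco activity through a
bundle-sheath leakage conductance ``gbs``. The two rates are combined as
a minimum. The bundle-sheath O2-evolution fraction is fixed at zero,
which keeps both quadratics monic. Simulation only: no C4 fitting is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as k
from .fvcb import DomainError, electron_transport


class ConfigurationError(ValueError):
    """Raised when a required parameter set is missing or inconsistent."""


@dataclass(frozen=True)
class C4Params:
    """Parameters of the C4 model (rates at 25 C, umol m-2 s-1).

    ``x`` partitions total electron transport between PEP regeneration
    (mesophyll) and the C3 cycle (bundle sheath). ``frm`` is the fraction
    of leaf respiration attributed to the mesophyll.
    """

    vcmax: float = 60.0       # bundle-sheath Rubisco capacity
    vpmax: float = 120.0      # PEP carboxylation capacity
    vpr: float = 80.0         # PEP regeneration-limited rate
    jmax: float = 400.0       # max whole-chain electron transport
    rd: float = 1.0           # leaf mitochondrial respiration
    frm: float = 0.5          # mesophyll fraction of rd
    kp: float = 80.0          # PEP-carboxylase Michaelis constant (umol mol-1)
    kc: float = 650.0         # Rubisco Kc (umol mol-1)
    ko: float = 450.0         # Rubisco Ko (mmol mol-1)
    om: float = 210.0         # bundle-sheath O2 (mmol mol-1)
    gbs: float = 3e-3         # bundle-sheath conductance (mol m-2 s-1)
    x: float = 0.4            # electron-transport partitioning factor
    gamma_star: float = 1.93e-4  # half reciprocal Rubisco specificity (-)
    alpha: float = k.ALPHA_J
    theta_j: float = 0.7
    # Q10 temperature factors applied to the capacity parameters
    q10: float = 2.0

    def __post_init__(self):
        for name in ("vcmax", "vpmax", "vpr", "jmax", "kp", "kc", "ko",
                     "om", "gbs"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ConfigurationError(f"C4 parameter {name} must be > 0")
        if not (0.0 < self.x < 1.0):
            raise ConfigurationError("x must be in (0, 1)")


def _smaller_root(b, c):
    # monic quadratic A^2 + b A + c = 0, physically valid (smaller) root
    disc = np.maximum(b * b - 4.0 * c, 0.0)
    return (-b - np.sqrt(disc)) / 2.0


def aci_c4(ci, params: C4Params | None = None, tleaf=25.0,
           par=k.PAR_SATURATING):
    """Net C4 assimilation An (umol m-2 s-1) at intercellular CO2 ``ci``.

    Mesophyll CO2 is taken equal to Ci (large mesophyll conductance).
    Capacities are scaled with a Q10 of ``params.q10`` from 25 C.
    """
    if params is None:
        params = C4Params()
    if not isinstance(params, C4Params):
        raise ConfigurationError("params must be a C4Params instance")
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise DomainError("ci must be >= 0")

    ft = params.q10 ** ((tleaf - 25.0) / 10.0)
    vcmax = params.vcmax * ft
    vpmax = params.vpmax * ft
    rd = params.rd * ft
    rm = params.frm * rd
    om = params.om * 1000.0  # to umol mol-1, same basis as gamma_star
    kk = params.kc * (1.0 + om / (params.ko * 1000.0))
    cm = ci

    # PEP carboxylation rate, capped by PEP regeneration
    vp = np.minimum(cm * vpmax / (cm + params.kp), params.vpr)

    # enzyme-limited rate
    t1 = vp - rm + params.gbs * cm
    t2 = vcmax - rd
    b = -(t1 + t2 + params.gbs * kk)
    c = t1 * t2 - (vcmax * params.gbs * params.gamma_star * om
                   + rd * params.gbs * kk)
    ac = _smaller_root(b, c)

    # light-limited rate: Vcmax -> (1-x)J/3, Vp -> xJ/2, K -> 7 gamma* Om / 3
    jt = electron_transport(par, params.jmax * ft, params.alpha,
                            params.theta_j)
    vj = (1.0 - params.x) * jt / 3.0
    t1j = params.x * jt / 2.0 - rm + params.gbs * cm
    t2j = vj - rd
    kj = 7.0 * params.gamma_star * om / 3.0
    bj = -(t1j + t2j + params.gbs * kj)
    cj = t1j * t2j - (vj * params.gbs * params.gamma_star * om
                      + rd * params.gbs * kj)
    aj = _smaller_root(bj, cj)

    an = np.minimum(ac, aj)
    return an if an.ndim else float(an)
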