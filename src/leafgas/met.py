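"""Meteorological unit conversions for gas-exchange work.

Saturation vapour pressure uses a Magnus-type formula
(esat = 0.61078 exp(17.269 T / (237.3 + T)), T in C, esat in kPa).
All humidity conversions are mutually consistent round trips built on it.
"""

from __future__ import annotations

import numpy as np

from .fvcb import DomainError

__all__ = [
    "esat",
    "rh_to_vpd",
    "vpd_to_rh",
    "dew_to_vpd",
    "vpd_to_dew",
    "vpd_from_tair_empirical",
]

_MAGNUS_A = 0.61078   # kPa
_MAGNUS_B = 17.269
_MAGNUS_C = 237.3     # C


def esat(t):
    """Saturation vapour pressure (kPa) at air temperature t (C)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < -40.0) or np.any(t > 60.0):
        raise DomainError("temperature outside [-40, 60] C")
    e = _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))
    return e if e.ndim else float(e)


def rh_to_vpd(rh, tair):
    """Vapour pressure deficit (kPa) from relative humidity (%) and Tair."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise DomainError("rh must be in [0, 100] %")
    out = esat(tair) * (1.0 - rh / 100.0)
    return out if np.ndim(out) else float(out)


def vpd_to_rh(vpd, tair):
    """Relative humidity (%) from vapour pressure deficit (kPa) and Tair."""
    vpd = np.asarray(vpd, dtype=float)
    es = esat(tair)
    if np.any(vpd < 0.0) or np.any(vpd > es):
        raise DomainError("vpd must be in [0, esat(tair)]")
    out = 100.0 * (1.0 - vpd / es)
    return out if np.ndim(out) else float(out)


def dew_to_vpd(dewpoint, tair):
    """Vapour pressure deficit (kPa) from dewpoint and air temperature."""
    dewpoint = np.asarray(dewpoint, dtype=float)
    if np.any(dewpoint > np.asarray(tair, dtype=float)):
        raise DomainError("dewpoint cannot exceed tair")
    out = esat(tair) - esat(dewpoint)
    return out if np.ndim(out) else float(out)


def vpd_to_dew(vpd, tair):
    """Dewpoint temperature (C) from VPD (kPa), inverting the Magnus form."""
    ea = esat(tair) - np.asarray(vpd, dtype=float)
    if np.any(ea <= 0):
        raise DomainError("vpd must be below esat(tair)")
    x = np.log(ea / _MAGNUS_A)
    out = _MAGNUS_C * x / (_MAGNUS_B - x)
    return out if np.ndim(out) else float(out)


def vpd_from_tair_empirical(tair):
    """Empirical field relation between air temperature and VPD.

    D = 0.000605 Tair^2.39 (kPa); captures the strong positive covariance
    of D and temperature in field conditions, used to drive the coupled
    model along a realistic Tleaf-D trajectory.
    """
    tair = np.asarray(tair, dtype=float)
    if np.any(tair <= 0.0):
        raise DomainError("tair must be > 0 C for the empirical D relation")
    out = 0.000605 * tair ** 2.39
    return out if out.ndim else float(out)
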