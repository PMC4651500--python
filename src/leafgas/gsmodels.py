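"""Ball-Berry-type stomatal conductance models: prediction and fitting.

Three variants of ``gs = g0 + g1 f(env) An / Ca`` are supported (gs on the
H2O basis, mol m-2 s-1):

- ``ball_berry_rh``: f = RH/100 (fractional relative humidity at the leaf
  surface, approximated by air RH)
- ``leuning_d0``:    f = 1/(1 + D/D0)
- ``medlyn_opti``:   gs = g0 + 1.6 (1 + g1/sqrt(D)) An/Ca — the optimality
  based model; here the 1.6 diffusivity ratio is explicit, so g1 has units
  kPa^0.5, while for the other two variants any diffusivity convention is
  absorbed into the dimensionless g1.

Given a fixed D0, all three variants are linear in (g0, g1), so fitting
uses ordinary least squares, which also supplies standard errors and
t-based confidence intervals. ``BallBerryModel`` follows the scikit-learn
estimator protocol; ``fit_bb`` is a functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .fvcb import DomainError

__all__ = [
    "VARIANTS",
    "BallBerryModel",
    "GsFitResult",
    "gs_predict",
    "fit_bb",
    "ite_closed_form",
    "compare_gs_models",
]

VARIANTS = ("ball_berry_rh", "leuning_d0", "medlyn_opti")
_ALIASES = {"ballberry": "ball_berry_rh", "bb": "ball_berry_rh",
            "bbleuning": "leuning_d0", "leuning": "leuning_d0",
            "bbopti": "medlyn_opti", "medlyn": "medlyn_opti"}


def _canon(variant: str) -> str:
    v = variant.lower().replace("-", "_")
    v = _ALIASES.get(v.replace("_", ""), v)
    if v not in VARIANTS:
        raise ValueError(f"unknown gs model variant {variant!r}; "
                         f"choose from {VARIANTS}")
    return v


def gs_predict(variant, g0, g1, an, ca, d=None, rh=None, d0=1.5):
    """Predicted stomatal conductance to H2O (mol m-2 s-1)."""
    variant = _canon(variant)
    an = np.asarray(an, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise DomainError("ca must be > 0")
    if variant == "ball_berry_rh":
        if rh is None:
            raise DomainError("ball_berry_rh requires rh")
        rh = np.asarray(rh, dtype=float)
        if np.any(rh < 0) or np.any(rh > 100):
            raise DomainError("rh must be in [0, 100] %")
        gs = g0 + g1 * an * (rh / 100.0) / ca
    else:
        if d is None:
            raise DomainError(f"{variant} requires d")
        d = np.asarray(d, dtype=float)
        if np.any(d <= 0):
            raise DomainError("d must be > 0 for D-based variants")
        if variant == "leuning_d0":
            if d0 is None or d0 <= 0:
                raise DomainError("leuning_d0 requires d0 > 0")
            gs = g0 + g1 * an / (ca * (1.0 + d / d0))
        else:  # medlyn_opti
            gs = g0 + 1.6 * (1.0 + g1 / np.sqrt(d)) * an / ca
    return gs if np.ndim(gs) else float(gs)


@dataclass
class GsFitResult:
    """Result of fitting one stomatal conductance model variant."""

    variant: str
    g1: float
    g0: float
    g0_fixed: bool
    standard_errors: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]  # 95%
    predicted_gs: np.ndarray
    rmse: float
    r_squared: float
    n_obs: int
    settings: dict[str, Any] = field(default_factory=dict)


class BallBerryModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for Ball-Berry-type gs models.

    Parameters
    ----------
    variant : str
        One of 'ball_berry_rh', 'leuning_d0', 'medlyn_opti' (aliases
        'BBOpti', 'BBLeuning', 'BallBerry' accepted).
    g0 : float or None
        Fixed residual conductance (mol m-2 s-1); None fits g0 freely.
    d0 : float
        Leuning VPD sensitivity parameter (kPa); only used by leuning_d0.

    Attributes
    ----------
    g1_, g0_ : float
    result_ : GsFitResult
    """

    def __init__(self, variant="medlyn_opti", g0=0.0, d0=1.5):
        self.variant = variant
        self.g0 = g0
        self.d0 = d0

    def _design(self, X: pd.DataFrame):
        variant = _canon(self.variant)
        cols = {c.lower(): c for c in X.columns}

        def col(name, required=True):
            if name not in cols:
                if required:
                    raise DomainError(
                        f"{variant} requires column {name!r}")
                return None
            return X[cols[name]].astype(float).to_numpy()

        an = col("an")
        ca = col("ca")
        if np.any(ca <= 0):
            raise DomainError("ca must be > 0")
        offset = np.zeros_like(an)
        if variant == "ball_berry_rh":
            rh = col("rh")
            slope_term = an * (rh / 100.0) / ca
        elif variant == "leuning_d0":
            d = col("d")
            if np.any(d <= 0):
                raise DomainError("d must be > 0")
            slope_term = an / (ca * (1.0 + d / self.d0))
        else:
            d = col("d")
            if np.any(d <= 0):
                raise DomainError("d must be > 0")
            offset = 1.6 * an / ca          # the g1-independent Medlyn term
            slope_term = 1.6 * an / (ca * np.sqrt(d))
        return slope_term, offset

    def fit(self, X, y):
        """Fit g1 (and g0 when free). X: frame with an, ca, d/rh; y: gs."""
        if not isinstance(X, pd.DataFrame):
            raise DomainError("X must be a DataFrame with named columns")
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise DomainError("X and y lengths differ")
        if len(y) < 3:
            raise DomainError("need at least 3 observations")
        slope_term, offset = self._design(X)
        if np.allclose(slope_term, 0.0):
            raise DomainError("gs model unidentifiable: regressor is all "
                              "zero (e.g. an = 0 everywhere)")

        free_g0 = self.g0 is None
        resp = y - offset - (0.0 if free_g0 else self.g0)
        design = sm.add_constant(slope_term) if free_g0 \
            else slope_term.reshape(-1, 1)
        ols = sm.OLS(resp, design).fit()
        ci95 = ols.conf_int(alpha=0.05)
        if free_g0:
            g0_hat, g1_hat = float(ols.params[0]), float(ols.params[1])
            ses = {"g0": float(ols.bse[0]), "g1": float(ols.bse[1])}
            cis = {"g0": (float(ci95[0][0]), float(ci95[0][1])),
                   "g1": (float(ci95[1][0]), float(ci95[1][1]))}
        else:
            g0_hat, g1_hat = float(self.g0), float(ols.params[0])
            ses = {"g0": 0.0, "g1": float(ols.bse[0])}
            cis = {"g0": (g0_hat, g0_hat),
                   "g1": (float(ci95[0][0]), float(ci95[0][1]))}

        pred = g0_hat + offset + g1_hat * slope_term
        resid = y - pred
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        r = np.corrcoef(y, pred)[0, 1] if np.std(pred) > 0 else 0.0

        self.g0_, self.g1_ = g0_hat, g1_hat
        self.result_ = GsFitResult(
            variant=_canon(self.variant), g1=g1_hat, g0=g0_hat,
            g0_fixed=not free_g0, standard_errors=ses,
            confidence_intervals=cis, predicted_gs=pred, rmse=rmse,
            r_squared=float(r ** 2), n_obs=len(y),
            settings={"d0": self.d0})
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise DomainError("estimator is not fitted")
        slope_term, offset = self._design(X)
        return self.g0_ + offset + self.g1_ * slope_term


def fit_bb(data: pd.DataFrame, variant="medlyn_opti", g0=0.0,
           d0=1.5) -> GsFitResult:
    """Fit one gs model variant to spot gas-exchange data.

    ``data`` needs columns gs, an, ca and d (or rh for the original
    Ball-Berry variant); gs must be the conductance to H2O.
    """
    cols = {c.lower(): c for c in data.columns}
    if "gs" not in cols:
        raise DomainError("data must contain a 'gs' column (H2O basis)")
    y = data[cols["gs"]].astype(float).to_numpy()
    est = BallBerryModel(variant=variant, g0=g0, d0=d0).fit(data, y)
    return est.result_


def ite_closed_form(ca, pa, g1, d):
    """Instantaneous transpiration efficiency An/E (umol CO2 mmol-1 H2O).

    Closed form for the optimality-based gs model with g0 = 0 and perfectly
    coupled transpiration E = gs D / Pa:
    ``ITE = Ca Pa / (1.6 (g1 sqrt(D) + D)) / 1000``, with Ca in umol mol-1
    and D, Pa in kPa. The factor 1000 converts mol H2O to mmol; multiply
    by 1000 for umol CO2 per mol H2O.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("d must be > 0")
    if np.any(np.asarray(pa, dtype=float) <= 0):
        raise DomainError("pa must be > 0")
    out = np.asarray(ca, dtype=float) * pa / (
        1.6 * (g1 * np.sqrt(d) + d)) / 1000.0
    return out if out.ndim else float(out)


def compare_gs_models(data: pd.DataFrame, g0=0.0, d0=1.5) -> pd.DataFrame:
    """Fit all three variants to the same data; one goodness-of-fit row each.

    Variants whose fit fails are kept as flagged rows rather than dropped.
    """
    rows = []
    for variant in VARIANTS:
        try:
            res = fit_bb(data, variant=variant, g0=g0, d0=d0)
            rows.append({"variant": variant, "g0": res.g0, "g1": res.g1,
                         "rmse": res.rmse, "r_squared": res.r_squared,
                         "ok": True, "error": ""})
        except (DomainError, ValueError) as err:
            rows.append({"variant": variant, "g0": np.nan, "g1": np.nan,
                         "rmse": np.nan, "r_squared": np.nan,
                         "ok": False, "error": str(err)})
    return pd.DataFrame(rows)
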