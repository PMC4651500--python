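"""Fit the FvCB model to measured A-Ci curves by nonlinear least squares.

The estimator fits (Vcmax, Jmax, Rd), normalised to 25 C by default with
per-observation leaf-temperature correction, by minimising the sum of
squared residuals of net assimilation. The smooth hyperbolic minimum of
the two limitation rates is fitted rather than the hard minimum, which
avoids the discontinuity at the limitation transition. Standard errors
and 95% t-based confidence intervals come from the linearised covariance
at the optimum; the Ci transition point is located afterwards by
root-finding on Ac(Ci) = Aj(Ci).

``FvCBEstimator`` follows the scikit-learn estimator protocol (fit /
predict / get_params); ``fit_aci`` and friends are thin functional
wrappers around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import constants as k
from .fvcb import (BiochemParams, DomainError, as_scalar, demand_at_ci,
                   limb_net_rate)

__all__ = [
    "FvCBEstimator",
    "AciFitResult",
    "FittingError",
    "estimate_starting_values",
    "fit_aci",
    "fit_aci_fixed_transition",
    "fit_acis_batch",
]


class FittingError(RuntimeError):
    """Raised when a curve cannot be fitted (degenerate data, no convergence)."""


def _as_curve_frame(X) -> pd.DataFrame:
    """Coerce input into a frame with columns ci, tleaf, par."""
    if isinstance(X, pd.DataFrame):
        df = X.copy()
        cols = {c.lower(): c for c in df.columns}
        if "ci" not in cols:
            raise FittingError("input must contain a 'ci' column")
        out = pd.DataFrame({"ci": df[cols["ci"]].astype(float).to_numpy()})
        out["tleaf"] = (df[cols["tleaf"]].astype(float).to_numpy()
                        if "tleaf" in cols else 25.0)
        out["par"] = (df[cols["par"]].astype(float).to_numpy()
                      if "par" in cols else k.PAR_SATURATING)
        return out
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = pd.DataFrame({"ci": X[:, 0]})
    out["tleaf"] = X[:, 1] if X.shape[1] > 1 else 25.0
    out["par"] = X[:, 2] if X.shape[1] > 2 else k.PAR_SATURATING
    return out


def _model_an(theta, ci, tleaf, par, base: BiochemParams, tcorrect: bool):
    """Predicted An for candidate (vcmax25, jmax25, rd25) per observation.

    Per-row Tleaf is always used for the kinetic constants (Km, GammaStar);
    when ``tcorrect`` is off the fitted capacities apply directly at the
    measurement temperature (their temperature responses are disabled).
    """
    vcmax, jmax, rd = theta
    p = base.with_(vcmax25=max(vcmax, 1e-12), jmax25=max(jmax, 1e-12),
                   rd25=max(rd, 0.0))
    if not tcorrect:
        p = p.with_(ea_vcmax=0.0, hd_vcmax=0.0, ea_jmax=0.0, hd_jmax=0.0,
                    ea_rd=0.0)
    an = np.empty(len(ci))
    # group identical (tleaf, par) conditions so curves at constant
    # conditions evaluate in one vectorised call
    key = pd.Series(list(zip(tleaf, par)))
    for (tl, q), idx in key.groupby(key).groups.items():
        an[np.asarray(idx)] = demand_at_ci(
            ci[np.asarray(idx)], p, tleaf=tl, par=q).an
    return an


def estimate_starting_values(curve: pd.DataFrame, rd0: float = 1.5,
                             tcorrect: bool = True):
    """Data-driven starting values (vcmax0, jmax0, rd0) for the NLS fit.

    Vcmax from single-point inversion of the Rubisco-limited form on the
    lowest-Ci points; Jmax from inversion of the RuBP-limited form (and
    the light response) on the highest-Ci points; rd0 a small positive
    default (or the supplied known value).
    """
    est = FvCBEstimator(tcorrect=tcorrect, rd_start=rd0)
    X, y = _split_xy(curve)
    df, y = est._validate(X, y)
    return est._starting_values(df, y, est._base())


@dataclass
class AciFitResult:
    """Result of one A-Ci curve fit."""

    estimates: dict[str, float]            # vcmax, jmax, rd (25 C basis)
    standard_errors: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]  # 95% t-based
    covariance: np.ndarray                 # 3x3, order (vcmax, jmax, rd)
    fitted_an: np.ndarray
    residuals: np.ndarray
    r_squared: float
    ssr: float
    ci_transition: float                   # umol mol-1 (nan if no crossing)
    converged: bool
    settings: dict[str, Any] = field(default_factory=dict)
    unreliable: tuple[str, ...] = ()       # params with no supporting limb
    curve_id: str | None = None

    def coef_row(self) -> dict[str, float]:
        row = {"curve_id": self.curve_id}
        for p in ("vcmax", "jmax", "rd"):
            lo, hi = self.confidence_intervals[p]
            row.update({p: self.estimates[p], f"{p}_se":
                        self.standard_errors[p], f"{p}_lo": lo, f"{p}_hi": hi})
        row.update({"r_squared": self.r_squared,
                    "ci_transition": self.ci_transition,
                    "converged": self.converged})
        return row


class FvCBEstimator(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for FvCB A-Ci curve fitting.

    Parameters
    ----------
    rd_fixed : float or None
        Fix dark respiration at a known (measured) value instead of
        estimating it. Must be >= 0.
    gm : float or None
        Mesophyll conductance (mol m-2 s-1); when given, the fitted Vcmax
        and Jmax are chloroplastic rates.
    tcorrect : bool
        Fit 25 C-normalised capacities with per-row temperature correction
        (default); if False, capacities apply at measurement temperature.
    citransition : float or None
        Fix the Rubisco/RuBP transition at this Ci instead of letting the
        hyperbolic-minimum fit locate it.
    base_params : BiochemParams or None
        Kinetic constants (Kc, Ko, GammaStar, Oi, alpha, thetas) and
        temperature-response settings; defaults used when None.
    multistart : bool
        Retry the fit from a grid of scaled starting values ({0.5, 1, 2}
        per parameter), keeping the best SSR, with early exit once extra
        starts stop improving the best SSR by more than 1e-10.
    bounds : dict or None
        Optional {param: (lo, hi)} box bounds overriding the defaults
        (all parameters constrained >= 0).

    Attributes
    ----------
    vcmax_, jmax_, rd_ : float
        Parameter estimates (umol m-2 s-1).
    result_ : AciFitResult
        Full fit result (SEs, CIs, covariance, transition point, ...).
    """

    def __init__(self, rd_fixed=None, gm=None, tcorrect=True,
                 citransition=None, base_params=None, multistart=True,
                 bounds=None, rd_start=1.5):
        self.rd_fixed = rd_fixed
        self.gm = gm
        self.tcorrect = tcorrect
        self.citransition = citransition
        self.base_params = base_params
        self.multistart = multistart
        self.bounds = bounds
        self.rd_start = rd_start

    # ---- internals ---------------------------------------------------
    def _base(self) -> BiochemParams:
        base = self.base_params if self.base_params is not None \
            else BiochemParams()
        return base.with_(gm=self.gm) if self.gm is not None else base

    def _validate(self, X, y):
        df = _as_curve_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(df):
            raise FittingError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise FittingError("an_obs contains non-finite values")
        if np.any(df["ci"] < 0):
            raise DomainError("ci must be >= 0")
        n_free = 2 if self.rd_fixed is not None else 3
        if len(df) < n_free + 2:
            raise FittingError(
                f"need at least {n_free + 2} observations, got {len(df)}")
        if df["ci"].nunique() < 2:
            raise FittingError("degenerate curve: all ci values identical")
        if self.rd_fixed is not None and self.rd_fixed < 0:
            raise DomainError("fixed rd must be >= 0")
        return df, y

    def _starting_values(self, df, y, base):
        """Invert each limb on its end of the curve for initial values."""
        rd0 = self.rd_fixed if self.rd_fixed is not None else self.rd_start
        order = np.argsort(df["ci"].to_numpy())
        ci = df["ci"].to_numpy()[order]
        tl = df["tleaf"].to_numpy()[order]
        q = df["par"].to_numpy()[order]
        a = y[order]
        n_end = max(2, min(3, len(ci) // 3))

        def invert(idx, limb):
            vals = []
            for i in idx:
                gs_ = base.gammastar_at(tl[i])
                gs_ = gs_ if not self.tcorrect else gs_  # per-row either way
                if ci[i] <= gs_ + 1.0:
                    continue
                gross = a[i] + rd0
                if gross <= 0:
                    continue
                if limb == "ac":
                    km = base.km_at(tl[i])
                    v = gross * (ci[i] + km) / (ci[i] - gs_)
                    if self.tcorrect:
                        v /= base.with_(vcmax25=1.0).vcmax_at(tl[i])
                    vals.append(v)
                else:
                    jj = 4.0 * gross * (ci[i] + 2.0 * gs_) / (ci[i] - gs_)
                    aq = base.alpha * q[i]
                    if aq > jj:  # invert the light response for Jmax
                        jm = jj * (base.theta_j * jj - aq) / (jj - aq)
                    else:
                        jm = jj * 1.2
                    if self.tcorrect:
                        jm /= base.with_(jmax25=1.0).jmax_at(tl[i])
                    vals.append(jm)
            return float(np.median(vals)) if vals else None

        vcmax0 = invert(range(n_end), "ac") or 50.0
        jmax0 = invert(range(len(ci) - n_end, len(ci)), "aj") or 1.8 * vcmax0
        return float(np.clip(vcmax0, 1.0, 1000.0)), \
            float(np.clip(jmax0, 1.0, 2000.0)), float(rd0)

    def _residual_fn(self, df, y, base):
        ci = df["ci"].to_numpy()
        tl = df["tleaf"].to_numpy() if np.ndim(df["tleaf"].to_numpy()) \
            else np.full(len(df), df["tleaf"])
        q = df["par"].to_numpy()
        ct = self.citransition
        fix_rd = self.rd_fixed

        def predict(theta_full):
            if ct is None:
                return _model_an(theta_full, ci, tl, q, base, self.tcorrect)
            # fixed transition: Rubisco limb below ct, RuBP limb above
            vcmax, jmax, rd = theta_full
            p = base.with_(vcmax25=max(vcmax, 1e-12),
                           jmax25=max(jmax, 1e-12), rd25=max(rd, 0.0))
            if not self.tcorrect:
                p = p.with_(ea_vcmax=0.0, hd_vcmax=0.0, ea_jmax=0.0,
                            hd_jmax=0.0, ea_rd=0.0)
            an = np.empty(len(ci))
            lo = ci < ct
            for mask, limb in ((lo, "ac"), (~lo, "aj")):
                for i in np.flatnonzero(mask):
                    an[i] = as_scalar(limb_net_rate(
                        ci[i], p, tleaf=tl[i], par=q[i], limb=limb))
            return an

        def expand(theta_free):
            if fix_rd is None:
                return theta_free
            return np.array([theta_free[0], theta_free[1], fix_rd])

        def resid(theta_free):
            return predict(expand(theta_free)) - y

        return predict, expand, resid

    # ---- API ---------------------------------------------------------
    def fit(self, X, y):
        """Fit the model. X: columns (ci[, tleaf[, par]]); y: observed An."""
        base = self._base()
        df, y = self._validate(X, y)
        if self.citransition is not None:
            ci = df["ci"].to_numpy()
            if (ci < self.citransition).sum() < 2 or \
                    (ci >= self.citransition).sum() < 2:
                raise FittingError(
                    "fixed ci transition leaves fewer than 2 points on a limb")

        predict, expand, resid = self._residual_fn(df, y, base)
        v0, j0, r0 = self._starting_values(df, y, base)

        default_bounds = {"vcmax": (0.0, np.inf), "jmax": (0.0, np.inf),
                          "rd": (0.0, np.inf)}
        if self.bounds:
            default_bounds.update(self.bounds)
        names = ["vcmax", "jmax"] + ([] if self.rd_fixed is not None
                                     else ["rd"])
        lo = [default_bounds[n][0] for n in names]
        hi = [default_bounds[n][1] for n in names]

        scalings = [(1.0, 1.0, 1.0)]
        if self.multistart:
            for sv in (0.5, 1.0, 2.0):
                for sj in (0.5, 1.0, 2.0):
                    for sr in (0.5, 1.0, 2.0):
                        if (sv, sj, sr) != (1.0, 1.0, 1.0):
                            scalings.append((sv, sj, sr))

        best = None
        stalls = 0
        for sv, sj, sr in scalings:
            theta0 = [np.clip(v0 * sv, lo[0] + 1e-9, None),
                      np.clip(j0 * sj, lo[1] + 1e-9, None)]
            if self.rd_fixed is None:
                theta0.append(max(r0 * sr, lo[2]))
            try:
                sol = optimize.least_squares(resid, theta0, bounds=(lo, hi),
                                             xtol=1e-12, ftol=1e-12,
                                             gtol=1e-12)
            except Exception:
                continue
            ssr = float(np.sum(sol.fun ** 2))
            if best is None or ssr < best[0] - 1e-10:
                best = (ssr, sol)
                stalls = 0
            else:
                stalls += 1
                if best[1].success and stalls >= 2:
                    break
        if best is None:
            raise FittingError("all fit attempts failed")
        ssr, sol = best
        converged = bool(sol.success)
        if not converged:
            warnings.warn("A-Ci fit did not converge from any start",
                          stacklevel=2)

        theta = expand(sol.x)
        fitted = predict(theta)
        residuals = fitted - y
        n, p = len(y), len(sol.x)
        dof = max(n - p, 1)
        s2 = ssr / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_free = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_free = s2 * np.linalg.pinv(jtj)
        cov = np.zeros((3, 3))
        free_idx = [0, 1] + ([] if self.rd_fixed is not None else [2])
        for a_, ia in enumerate(free_idx):
            for b_, ib in enumerate(free_idx):
                cov[ia, ib] = cov_free[a_, b_]
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        tcrit = stats.t.ppf(0.975, dof)

        names3 = ("vcmax", "jmax", "rd")
        estimates = dict(zip(names3, map(float, theta)))
        ses = dict(zip(names3, map(float, se)))
        cis = {nm: (estimates[nm] - tcrit * ses[nm],
                    estimates[nm] + tcrit * ses[nm]) for nm in names3}
        if self.rd_fixed is not None:
            cis["rd"] = (self.rd_fixed, self.rd_fixed)

        r = np.corrcoef(y, fitted)[0, 1] if np.std(fitted) > 0 else 0.0
        r2 = float(r ** 2)

        ci_trans = self.citransition if self.citransition is not None else \
            self._transition(df, estimates, base)

        unreliable = []
        if np.isfinite(ci_trans):
            ci_all = df["ci"].to_numpy()
            if not np.any(ci_all < ci_trans):
                unreliable.append("vcmax")
            if not np.any(ci_all >= ci_trans):
                unreliable.append("jmax")
        if unreliable:
            warnings.warn("no observations on the "
                          f"{' and '.join(unreliable)} limb; the reported "
                          "SE(s) are unreliable", stacklevel=2)

        self.vcmax_, self.jmax_, self.rd_ = (estimates["vcmax"],
                                             estimates["jmax"],
                                             estimates["rd"])
        self.n_features_in_ = 3
        self.result_ = AciFitResult(
            estimates=estimates, standard_errors=ses,
            confidence_intervals=cis, covariance=cov, fitted_an=fitted,
            residuals=residuals, r_squared=r2, ssr=ssr,
            ci_transition=float(ci_trans), converged=converged,
            settings={"rd_fixed": self.rd_fixed, "gm": self.gm,
                      "tcorrect": self.tcorrect,
                      "citransition": self.citransition},
            unreliable=tuple(unreliable))
        return self

    def _fitted_params(self) -> BiochemParams:
        base = self._base()
        p = base.with_(vcmax25=max(self.vcmax_, 1e-12),
                       jmax25=max(self.jmax_, 1e-12), rd25=max(self.rd_, 0.0))
        if not self.tcorrect:
            p = p.with_(ea_vcmax=0.0, hd_vcmax=0.0, ea_jmax=0.0,
                        hd_jmax=0.0, ea_rd=0.0)
        return p

    def _transition(self, df, estimates, base) -> float:
        """Ci where the Rubisco and RuBP gross rates cross."""
        p = base.with_(vcmax25=max(estimates["vcmax"], 1e-12),
                       jmax25=max(estimates["jmax"], 1e-12),
                       rd25=max(estimates["rd"], 0.0))
        if not self.tcorrect:
            p = p.with_(ea_vcmax=0.0, hd_vcmax=0.0, ea_jmax=0.0,
                        hd_jmax=0.0, ea_rd=0.0)
        tl = float(np.mean(df["tleaf"]))
        q = float(np.mean(df["par"]))

        def diff(ci):
            d = demand_at_ci(ci, p, tleaf=tl, par=q)
            return as_scalar((d.ac) - np.asarray(d.aj))

        lo = p.gammastar_at(tl) + 1.0
        hi = 2000.0
        try:
            if diff(lo) * diff(hi) > 0:
                return float("nan")
            return float(optimize.brentq(diff, lo, hi, xtol=1e-8))
        except Exception:
            return float("nan")

    def predict(self, X):
        """Predicted An at the fitted parameters."""
        if not hasattr(self, "result_"):
            raise FittingError("estimator is not fitted")
        df = _as_curve_frame(X)
        p = self._fitted_params()
        an = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            an[i] = as_scalar((demand_at_ci(
                row.ci, p, tleaf=row.tleaf, par=row.par).an))
        return an


def _split_xy(curve: pd.DataFrame):
    cols = {c.lower(): c for c in curve.columns}
    an_col = cols.get("an") or cols.get("photo")
    if an_col is None:
        raise FittingError("curve must contain an 'an' (or 'Photo') column")
    y = curve[an_col].astype(float).to_numpy()
    return curve, y


def fit_aci(curve: pd.DataFrame, rd_fixed=None, gm=None, tcorrect=True,
            citransition=None, **kwargs) -> AciFitResult:
    """Fit one A-Ci curve; columns: an (or Photo), ci, optional tleaf, par."""
    X, y = _split_xy(curve)
    est = FvCBEstimator(rd_fixed=rd_fixed, gm=gm, tcorrect=tcorrect,
                        citransition=citransition, **kwargs).fit(X, y)
    return est.result_


def fit_aci_fixed_transition(curve: pd.DataFrame, ci_transition: float,
                             **kwargs) -> AciFitResult:
    """Fit with the Rubisco/RuBP transition fixed at a given Ci."""
    ci = _as_curve_frame(curve)["ci"].to_numpy()
    if not (ci.min() <= ci_transition <= ci.max()):
        raise FittingError("ci_transition outside the observed ci range")
    return fit_aci(curve, citransition=ci_transition, **kwargs)


def fit_acis_batch(table: pd.DataFrame, group_key: str,
                   **kwargs) -> dict[str, AciFitResult | FittingError]:
    """Fit many curves at once, one per level of ``group_key``.

    Per-group failures are isolated: the failing group maps to the raised
    error, other groups fit normally.
    """
    if len(table) == 0:
        raise FittingError("empty table")
    if group_key not in table.columns:
        raise FittingError(f"group column {group_key!r} not in table")
    out: dict[str, AciFitResult | FittingError] = {}
    for gid, sub in table.groupby(group_key, sort=False):
        try:
            res = fit_aci(sub, **kwargs)
            res.curve_id = str(gid)
            out[str(gid)] = res
        except (FittingError, DomainError) as err:
            warnings.warn(f"curve {gid!r} failed to fit: {err}", stacklevel=2)
            out[str(gid)] = err
    return out


def plot_aci_fit(result: AciFitResult, curve: pd.DataFrame, ax=None):
    """Diagnostic plot: measured An, fitted curve and the two limitation
    rates against Ci. Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    from .fvcb import limb_net_rate

    if ax is None:
        _, ax = plt.subplots()
    df = _as_curve_frame(curve)
    _, y = _split_xy(curve)
    est = FvCBEstimator(**{k: result.settings.get(k) for k in
                           ("rd_fixed", "gm", "tcorrect", "citransition")})
    est.vcmax_, est.jmax_, est.rd_ = (result.estimates["vcmax"],
                                      result.estimates["jmax"],
                                      result.estimates["rd"])
    est.result_ = result
    p = est._fitted_params()
    tl, q = float(df["tleaf"].mean()), float(df["par"].mean())
    grid = np.linspace(max(df["ci"].min(), 1.0), df["ci"].max(), 200)
    ax.plot(grid, np.asarray(demand_at_ci(grid, p, tleaf=tl, par=q).an),
            "k-", label="fitted")
    for limb, style in (("ac", "C0--"), ("aj", "C1--")):
        ax.plot(grid, np.asarray(limb_net_rate(grid, p, tleaf=tl, par=q,
                                               limb=limb)), style,
                label=limb.capitalize() + " - Rd")
    ax.plot(df["ci"], y, "ko", mfc="none", label="measured")
    ax.set_xlabel("Ci (umol mol$^{-1}$)")
    ax.set_ylabel("An (umol m$^{-2}$ s$^{-1}$)")
    ax.legend(frameon=False)
    return ax


def coef_table(results: dict[str, AciFitResult | FittingError]
               ) -> pd.DataFrame:
    """One row per curve with estimates, SEs, CIs, R2 and convergence."""
    rows = []
    for gid, res in results.items():
        if isinstance(res, AciFitResult):
            rows.append(res.coef_row())
        else:
            rows.append({"curve_id": gid, "converged": False,
                         "error": str(res)})
    return pd.DataFrame(rows)
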