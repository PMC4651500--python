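"""Synthetic gas-exchange data with known truth.

Generates A-Ci response curves and "spot" gas-exchange tables (records at
prevailing conditions) from the package's own forward models, with
additive Gaussian noise on the response only (the fitters assume
response-only error). Every generator stores the generating truth next to
the data, so fitter round trips can be tested without any external
dataset.

Default magnitudes follow typical C3 broadleaf values (Vcmax ~ 47,
Jmax ~ 105, Rd ~ 1.3 umol m-2 s-1); the default A-Ci design is 12 Ci
points spanning 40-1500 umol mol-1, the shape of a standard chamber
CO2-response protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupled import EnvironmentalDrivers, NoSolutionError, photosyn_coupled
from .fvcb import BiochemParams, demand_at_ci
from .met import esat

__all__ = [
    "DEFAULT_CI_GRID",
    "default_truth",
    "make_aci_curve",
    "make_aci_batch",
    "make_spot_data",
]

#: 12 Ci points spanning [40, 1500], the usual chamber protocol shape
DEFAULT_CI_GRID = np.array([40.0, 75.0, 110.0, 150.0, 200.0, 275.0, 350.0,
                            450.0, 600.0, 800.0, 1100.0, 1500.0])


def default_truth() -> BiochemParams:
    """Default generating truth for A-Ci curves."""
    return BiochemParams(vcmax25=47.0, jmax25=105.0, rd25=1.3)


def make_aci_curve(truth: BiochemParams | None = None, ci_grid=None,
                   tleaf: float = 25.0, par: float = 1800.0,
                   noise_sd: float = 0.0, seed: int | None = None,
                   curve_id: str = "1") -> tuple[pd.DataFrame, BiochemParams]:
    """One synthetic A-Ci curve plus its generating truth.

    Returns a frame with gas-analyser-style columns (Photo, Ci, Tleaf,
    PARi) plus the noise-free truth column An_true and the curve label.
    Same seed implies identical output.
    """
    truth = truth if truth is not None else default_truth()
    ci = np.asarray(DEFAULT_CI_GRID if ci_grid is None else ci_grid,
                    dtype=float)
    rng = np.random.default_rng(seed)
    an_true = np.asarray(demand_at_ci(ci, truth, tleaf=tleaf, par=par).an)
    an_obs = an_true + rng.normal(0.0, noise_sd, size=ci.shape) \
        if noise_sd > 0 else an_true.copy()
    df = pd.DataFrame({"Curve": curve_id, "Photo": an_obs, "Ci": ci,
                       "Tleaf": tleaf, "PARi": par, "An_true": an_true})
    return df, truth


def make_aci_batch(truths: dict[str, BiochemParams], noise_sd: float = 0.0,
                   seed: int | None = None, **kwargs) -> pd.DataFrame:
    """Several curves in one long table, labelled by the 'Curve' column."""
    rng = np.random.default_rng(seed)
    frames = []
    for cid, truth in truths.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        df, _ = make_aci_curve(truth, noise_sd=noise_sd, seed=sub_seed,
                               curve_id=cid, **kwargs)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _default_drivers() -> pd.DataFrame:
    """Wide-ranging driver table (PAR, Tleaf, D) for spot data."""
    par = [400.0, 800.0, 1200.0, 1800.0]
    tleaf = [15.0, 22.0, 29.0, 35.0]
    d = [0.6, 1.0, 1.6, 2.4]
    rows = [(q, t, dd) for q in par for t in tleaf for dd in d]
    df = pd.DataFrame(rows, columns=["par", "tleaf", "d"])
    df["ca"] = 400.0
    return df


def make_spot_data(g0: float = 0.0, g1: float = 4.0,
                   variant: str = "medlyn_opti", d0: float = 1.5,
                   biochem: BiochemParams | None = None, drivers=None,
                   noise_sd: float = 0.0, seed: int | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Spot gas-exchange records generated from the coupled model.

    An comes from solving the coupled model under each driver row with the
    given gs-model truth; the observed conductance is the model gs plus
    Gaussian noise. Returns the table (analyser-style columns Cond, Photo,
    CO2S, VpdL, RH_S, Tleaf, PARi) and the truth record.
    """
    biochem = biochem if biochem is not None else default_truth()
    drivers = _default_drivers() if drivers is None else drivers.copy()
    rng = np.random.default_rng(seed)
    rows = []
    for r in drivers.itertuples(index=False):
        env = EnvironmentalDrivers(par=r.par, tleaf=r.tleaf, vpd=r.d,
                                   ca=r.ca)
        try:
            sol = photosyn_coupled(env, biochem, variant=variant, g0=g0,
                                   g1=g1, d0=d0)
        except NoSolutionError:
            continue
        # leaf-surface RH approximated by air RH, same convention as the
        # coupled solver's ball_berry_rh path
        rh = float(np.clip(100.0 * (1.0 - r.d / esat(r.tleaf)), 0.0, 100.0))
        rows.append({"Photo": sol.an, "gs_true": sol.gs, "CO2S": r.ca,
                     "VpdL": r.d, "Tleaf": r.tleaf, "PARi": r.par,
                     "RH_S": rh})
    df = pd.DataFrame(rows)
    noise = rng.normal(0.0, noise_sd, size=len(df)) if noise_sd > 0 else 0.0
    df["Cond"] = df["gs_true"] + noise
    truth = {"g0": g0, "g1": g1, "variant": variant, "d0": d0,
             "biochem": biochem}
    return df, truth
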