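"""Tabular I/O with gas-analyser column conventions.

Portable gas-exchange instruments export CSV-like tables with
conventional headers (Photo, Cond, Ci, CO2S, Tleaf, PARi, VpdL, ...).
``ColumnMapping`` maps those file columns onto the package's logical
names; ``read_gas_exchange`` loads, validates and filters a file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fvcb import BiochemParams

log = logging.getLogger("leafgas")

__all__ = ["ColumnMapping", "read_gas_exchange", "write_table",
           "load_biochem_params", "save_biochem_params"]


@dataclass(frozen=True)
class ColumnMapping:
    """Logical name -> file column name. Defaults follow common analyser
    headers."""

    an: str = "Photo"
    gs: str = "Cond"
    ci: str = "Ci"
    ca: str = "CO2S"
    tleaf: str = "Tleaf"
    par: str = "PARi"
    d: str = "VpdL"
    rh: str = "RH_S"
    group: str = "Curve"

    def __post_init__(self):
        names = [getattr(self, f.name) for f in fields(self)]
        if len(set(names)) != len(names):
            raise ValueError("mapped column names must be unique")

    def as_dict(self) -> dict[str, str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def read_gas_exchange(path, mapping: ColumnMapping | None = None,
                      required: tuple[str, ...] = ("an", "ci")
                      ) -> pd.DataFrame:
    """Read a gas-exchange CSV, rename to logical names, drop bad rows.

    Columns listed in ``required`` must be present (an explicit error
    names the missing file column otherwise); rows with non-finite values
    in any required column are dropped with a logged count. Optional
    mapped columns are carried through when present.
    """
    mapping = mapping or ColumnMapping()
    df = pd.read_csv(path)
    rename = {}
    for logical, colname in mapping.as_dict().items():
        if colname in df.columns:
            rename[colname] = logical
        elif logical in required:
            raise KeyError(
                f"required column {colname!r} (-> {logical}) missing "
                f"from {path}")
    out = df.rename(columns=rename)
    req = list(required)
    numeric = [c for c in rename.values() if c != "group"]
    for c in numeric:
        out[c] = pd.to_numeric(out[c], errors="coerce")
    keep = np.ones(len(out), dtype=bool)
    for c in req:
        keep &= np.isfinite(out[c].to_numpy(dtype=float))
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d row(s) with non-finite values in %s",
                    dropped, req)
    out = out.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"no usable rows in {path}")
    return out


def write_table(df: pd.DataFrame, path, precision: int = 6) -> None:
    """Write a CSV with a fixed number of significant digits."""
    df.to_csv(path, index=False, float_format=f"%.{precision}g")


def save_biochem_params(params: BiochemParams, path) -> None:
    """Save a parameter set as flat key-value YAML (or JSON by suffix)."""
    data = asdict(params)
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_biochem_params(path) -> BiochemParams:
    """Load a parameter set from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" \
            else yaml.safe_load(fh)
    known = {f.name for f in fields(BiochemParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
    return BiochemParams(**data)
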