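"""CSV and configuration round-trips for traces, pigment series and fits.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, mandatory header row.
Times are minutes everywhere.  Schemas:

* NPQ:   ``time_min, npq, se, replicate, label``
* HPLC:  ``time_min, pigment, delta_mmol_per_molChl, se, label``

Parameter configs are flat YAML mappings whose keys are exactly the
``KineticParameters`` field names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .model import KineticParameters
from .observables import HPLCSeries, NPQTrace, PIGMENTS
from .protocols import LightProtocol, parse_protocol

__all__ = [
    "SchemaError",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "load_params",
    "save_params",
    "save_fit_result",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A data file does not match the expected column schema."""


_NPQ_COLS = ("time_min", "npq")
_HPLC_COLS = ("time_min", "pigment", "delta_mmol_per_molChl")


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = pd.to_numeric(df[col], errors="coerce")


def _check_monotone(times: np.ndarray, path: PathLike) -> None:
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise SchemaError(f"{path}: times not strictly increasing at row {int(bad[0]) + 3}")


def read_timeseries_csv(path: PathLike, kind: str,
                        protocol: Optional[str] = None):
    """Read a validated NPQ trace or HPLC series from CSV.

    ``kind`` is ``"npq"`` (returns a list of :class:`NPQTrace`, one per
    replicate) or ``"hplc"`` (returns an :class:`HPLCSeries`).  The SE
    column is optional.  An optional protocol string is attached to the
    result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    prot = parse_protocol(protocol) if protocol else None

    if kind == "npq":
        missing = [c for c in _NPQ_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        _check_numeric(df, ["time_min", "npq"] + (["se"] if "se" in df else []), path)
        if "replicate" not in df.columns:
            df["replicate"] = 0
        traces = []
        for rep, sub in df.groupby("replicate", sort=True):
            sub = sub.reset_index(drop=True)
            _check_monotone(sub["time_min"].to_numpy(), path)
            traces.append(NPQTrace(
                times=sub["time_min"].to_numpy(),
                npq=sub["npq"].to_numpy(),
                se=sub["se"].to_numpy() if "se" in sub else None,
                label=str(sub["label"].iloc[0]) if "label" in sub else "",
                replicate=int(rep),
                protocol=prot,
            ))
        return traces

    if kind == "hplc":
        missing = [c for c in _HPLC_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        _check_numeric(df, ["time_min", "delta_mmol_per_molChl"]
                       + (["se"] if "se" in df else []), path)
        delta, se = {}, {}
        times = None
        for x in PIGMENTS:
            sub = df[df["pigment"] == x].reset_index(drop=True)
            if sub.empty:
                raise SchemaError(f"{path}: no rows for pigment {x!r}")
            t = sub["time_min"].to_numpy()
            _check_monotone(t, path)
            if times is None:
                times = t
            elif not np.array_equal(times, t):
                raise SchemaError(f"{path}: pigments sampled at different times")
            delta[x] = sub["delta_mmol_per_molChl"].to_numpy()
            if "se" in sub:
                se[x] = sub["se"].to_numpy()
        return HPLCSeries(
            times=times, delta=delta, se=se or None,
            label=str(df["label"].iloc[0]) if "label" in df else "",
            protocol=prot,
        )

    raise ValueError(f"unknown kind {kind!r}; expected 'npq' or 'hplc'")


def write_timeseries_csv(path: PathLike, data) -> None:
    """Write NPQ traces (a single trace or a list) or an HPLC series to CSV."""
    path = Path(path)
    if isinstance(data, NPQTrace):
        data = [data]
    if isinstance(data, (list, tuple)) and all(isinstance(t, NPQTrace) for t in data):
        frames = []
        for tr in data:
            frames.append(pd.DataFrame({
                "time_min": tr.times,
                "npq": tr.npq,
                "se": tr.se if tr.se is not None else np.nan,
                "replicate": tr.replicate,
                "label": tr.label,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    if isinstance(data, HPLCSeries):
        rows = []
        for x in PIGMENTS:
            rows.append(pd.DataFrame({
                "time_min": data.times,
                "pigment": x,
                "delta_mmol_per_molChl": data.delta[x],
                "se": data.se[x] if data.se else np.nan,
                "label": data.label,
            }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        return
    raise TypeError(f"cannot serialize object of type {type(data).__name__}")


def load_params(path: PathLike) -> KineticParameters:
    """Load kinetic parameters from a flat YAML (or JSON) mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a flat key/value mapping")
    return KineticParameters.from_dict(data)


def save_params(path: PathLike, params: KineticParameters) -> None:
    """Write kinetic parameters as a flat YAML mapping (exact field names)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def save_fit_result(prefix: PathLike, fit: FitResult) -> List[Path]:
    """Serialize a fit to ``<prefix>.csv`` (parameter table) + ``<prefix>.json``.

    The CSV holds one row per free parameter (estimate and interval); the
    JSON sidecar carries the objective, per-sequence RMSDs, the full point
    parameter set and optimizer metadata.
    """
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    fit.to_frame().to_csv(csv_path, index=False)
    payload = {
        "objective": fit.objective,
        "rmsd_per_sequence": fit.rmsd_per_sequence,
        "params": fit.params.to_dict(),
        "se": fit.se,
        "meta": {k: v for k, v in fit.meta.items()},
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return [csv_path, json_path]
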