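"""CSV and JSON serialization of profiles and space-time fields.

Long-format CSV with header ``t,x,c`` is the interchange format: profiles at
different times live on different x-grids (the domain grows), so a wide table
would be ragged.  Floats are written with 17 significant digits, which
round-trips IEEE doubles bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import ConcentrationProfile, SpaceTimeField
from .core import ModelParameters

__all__ = ["field_to_frame", "frame_to_field", "write_csv", "read_csv",
           "write_json", "read_json"]

_FLOAT_FMT = "%.17g"


def field_to_frame(fld: SpaceTimeField) -> pd.DataFrame:
    """Flatten a field into a long-format (t, x, c) DataFrame."""
    parts = [
        pd.DataFrame({"t": np.full(p.x.size, p.t), "x": p.x, "c": p.c})
        for p in fld.profiles
    ]
    if not parts:
        return pd.DataFrame(columns=["t", "x", "c"])
    return pd.concat(parts, ignore_index=True)


def frame_to_field(
    df: pd.DataFrame, params: Optional[ModelParameters] = None
) -> SpaceTimeField:
    """Rebuild a field from a long-format (t, x, c) table.

    Domain length is taken as the largest x at each time when no generating
    parameter set is supplied (measured data).
    """
    for col in ("t", "x", "c"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    times = np.array(sorted(df["t"].unique()), dtype=float)
    profiles = []
    for t in times:
        sub = df[df["t"] == t].sort_values("x")
        x = sub["x"].to_numpy(dtype=float)
        c = sub["c"].to_numpy(dtype=float)
        if params is not None:
            from .core import tissue_length

            L = float(tissue_length(params, t))
        else:
            L = float(x[-1])
        profiles.append(ConcentrationProfile(t=float(t), L=L, x=x, c=c))
    return SpaceTimeField(times=times, profiles=profiles, params=params)


def write_csv(fld: SpaceTimeField, path: Union[str, Path]) -> None:
    """Write a field as long-format CSV, atomically (write then rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    field_to_frame(fld).to_csv(tmp, index=False, float_format=_FLOAT_FMT)
    tmp.replace(path)


def read_csv(
    path: Union[str, Path], params: Optional[ModelParameters] = None
) -> SpaceTimeField:
    # round_trip parser: the default fast path is off by a few ULP, which
    # breaks the bit-for-bit CSV round-trip contract
    return frame_to_field(
        pd.read_csv(path, float_precision="round_trip"), params=params
    )


def field_to_record(fld: SpaceTimeField) -> dict:
    return {
        "params": fld.params.to_dict() if fld.params is not None else None,
        "times": [float(t) for t in fld.times],
        "profiles": [[list(map(float, p.x)), list(map(float, p.c))] for p in fld.profiles],
    }


def record_to_field(rec: dict) -> SpaceTimeField:
    params = (
        ModelParameters.from_dict(rec["params"]) if rec.get("params") else None
    )
    times = np.asarray(rec["times"], dtype=float)
    profiles = []
    for t, (x, c) in zip(times, rec["profiles"]):
        x = np.asarray(x, dtype=float)
        if params is not None:
            from .core import tissue_length

            L = float(tissue_length(params, t))
        else:
            L = float(x[-1])
        profiles.append(ConcentrationProfile(t=float(t), L=L, x=x, c=np.asarray(c, dtype=float)))
    return SpaceTimeField(times=times, profiles=profiles, params=params)


def write_json(fld: SpaceTimeField, path: Union[str, Path]) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(field_to_record(fld)))
    tmp.replace(path)


def read_json(path: Union[str, Path]) -> SpaceTimeField:
    return record_to_field(json.loads(Path(path).read_text()))
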