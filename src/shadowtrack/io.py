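"""Track CSV readers and writers.

Dialect: header ``t,x[,y[,z]][,signal]`` with ``t`` in seconds (float),
coordinates in meters, decimal point '.', UTF-8.  ``signal`` is 1 for a
device-logged fix and 0 for an interpolated one.  Missing rows are simply
absent — the grid may be irregular.  Filtered trajectories are written as
``t,<coord>,<coord>_v,<coord>_a`` per coordinate (per-sample acceleration:
interval value at its left endpoint, final sample repeated), preceded by
``# key=value`` provenance comment lines.

Floats are serialized with ``repr`` (shortest round-trip form), so writing
the same object twice yields byte-identical files and a read-back
round-trips bitwise.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .tracks import ObservationSeries, PhaseTrajectory

__all__ = ["read_track_csv", "write_track_csv", "COORD_NAMES"]

COORD_NAMES = ("x", "y", "z")


def _coord_names(d: int) -> Sequence[str]:
    if d <= 3:
        return COORD_NAMES[:d]
    return tuple(f"c{k}" for k in range(d))


def read_track_csv(path, coord_columns: Optional[Sequence[str]] = None,
                   exclude_interpolated: bool = False) -> ObservationSeries:
    """Read a track CSV into an :class:`ObservationSeries`.

    Coordinates default to whichever of ``x, y, z`` are present.  Rows with
    ``signal`` 0 get ``valid_flags`` False and are removed when
    ``exclude_interpolated`` is set.  Non-numeric cells and non-increasing
    timestamps raise :class:`InvalidInputError` naming the offending row.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "t" not in df.columns:
        raise InvalidInputError("track CSV must have a 't' column")
    if coord_columns is None:
        coord_columns = [c for c in COORD_NAMES if c in df.columns]
        if not coord_columns:
            raise InvalidInputError("no coordinate columns (x, y, z) found")
    missing = [c for c in coord_columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"coordinate columns {missing} not in file")
    numeric_cols = ["t"] + list(coord_columns)
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.argmax((converted.isna()).to_numpy()))
            raise InvalidInputError(
                f"non-numeric or missing value in column '{col}' at data "
                f"row {row}")
        df[col] = converted.astype(float)
    times = df["t"].to_numpy()
    if times.size >= 2:
        dt = np.diff(times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise InvalidInputError(
                f"timestamps not strictly increasing at data row {row} "
                f"(t={times[row]!r})")
    values = df[list(coord_columns)].to_numpy()
    if len(coord_columns) == 1:
        values = values[:, 0]
    flags = None
    if "signal" in df.columns:
        flags = pd.to_numeric(df["signal"], errors="coerce").to_numpy() == 1
    obs = ObservationSeries(times, values, valid_flags=flags)
    return obs.drop_invalid() if exclude_interpolated else obs


def _fmt(x: float) -> str:
    return repr(float(x))


def write_track_csv(obj: Union[ObservationSeries, PhaseTrajectory], path,
                    provenance: Optional[Mapping[str, object]] = None) -> None:
    """Write an observation series or a filtered trajectory.

    Observation series emit ``t,x[,y,z],signal``; trajectories emit
    ``t,<coord>,<coord>_v,<coord>_a`` per coordinate.  ``provenance``
    key/value pairs are written as leading ``# key=value`` comments.
    Formatting is deterministic: rewriting the same object is
    byte-identical.
    """
    lines = []
    if provenance:
        for key, val in provenance.items():
            lines.append(f"# {key}={val}")
    if isinstance(obj, ObservationSeries):
        d = obj.n_dims
        names = _coord_names(d)
        lines.append("t," + ",".join(names) + ",signal")
        vals = obj.values if obj.values.ndim == 2 else obj.values[:, None]
        for i in range(obj.n_samples):
            row = [_fmt(obj.times[i])]
            row += [_fmt(v) for v in vals[i]]
            row.append(str(int(obj.valid_flags[i])))
            lines.append(",".join(row))
    elif isinstance(obj, PhaseTrajectory):
        d = obj.n_dims
        names = _coord_names(d)
        header = ["t"]
        for name in names:
            header += [name, f"{name}_v", f"{name}_a"]
        lines.append(",".join(header))
        p = obj.positions if obj.positions.ndim == 2 else obj.positions[:, None]
        v = obj.velocities if obj.velocities.ndim == 2 else obj.velocities[:, None]
        a = obj.accelerations_per_sample
        a = a if a.ndim == 2 else a[:, None]
        for i in range(obj.n_samples):
            row = [_fmt(obj.times[i])]
            for k in range(d):
                row += [_fmt(p[i, k]), _fmt(v[i, k]), _fmt(a[i, k])]
            lines.append(",".join(row))
    else:
        raise InvalidInputError(
            "write_track_csv takes an ObservationSeries or PhaseTrajectory")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
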