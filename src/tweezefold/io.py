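"""Trajectory file formats and JSON result serialization.

Trajectories travel as delimited text (TSV/CSV) with ``#`` metadata header
lines and the columns ``time_s``, ``extension_nm``, ``force_pn``, or as HDF5
with one group per record under ``/records/<id>`` holding ``time``,
``extension`` and ``force`` datasets (metadata in group attributes).  Results
are JSON with explicit unit suffixes in every field name; serialization is
deterministic (sorted keys) so fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_trajectories_h5",
    "write_trajectories_h5",
    "to_jsonable",
    "save_json",
    "TrajectoryParseError",
]

_COLUMNS = ("time_s", "extension_nm", "force_pn")


class TrajectoryParseError(ValueError):
    """A trajectory file violates the expected layout."""


def _scalar_metadata(metadata: dict[str, Any]) -> dict[str, Any]:
    out = {}
    for k, v in metadata.items():
        if isinstance(v, (str, bool)):
            out[k] = v
        elif np.isscalar(v) and np.isreal(v):
            out[k] = float(v)
    return out


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a record as TSV with ``# key=value`` metadata header lines."""
    path = Path(path)
    meta = _scalar_metadata(traj.metadata)
    if traj.trap_separation_nm is not None:
        meta["trap_separation_nm"] = float(traj.trap_separation_nm)
    lines = [f"# {k}={meta[k]!r}" for k in sorted(meta)]
    df = pd.DataFrame(
        {
            "time_s": traj.time_s,
            "extension_nm": traj.extension_nm,
            "force_pn": traj.force_pn
            if traj.force_pn is not None
            else np.full(len(traj), np.nan),
        }
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a TSV/CSV record written by :func:`write_trajectory`.

    Legacy two-column (time, extension) files are accepted with a warning when
    the force is recorded in the metadata instead.  Non-uniform or
    non-monotone time bases are rejected.
    """
    path = Path(path)
    metadata: dict[str, Any] = {}
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                try:
                    metadata[k.strip()] = json.loads(v.strip().strip("'\""))
                except json.JSONDecodeError:
                    metadata[k.strip()] = v.strip().strip("'\"")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, skiprows=header_rows)
    except Exception as err:
        raise TrajectoryParseError(f"{path}: cannot parse table: {err}") from err
    if "time_s" not in df.columns or "extension_nm" not in df.columns:
        raise TrajectoryParseError(
            f"{path}: missing required columns time_s/extension_nm "
            f"(found {list(df.columns)})"
        )
    if "force_pn" in df.columns and not df["force_pn"].isna().all():
        force = df["force_pn"].to_numpy()
    elif "force_pn" in metadata:
        warnings.warn(
            f"{path.name}: legacy two-column record; using constant force from metadata"
        )
        force = np.full(len(df), float(metadata["force_pn"]))
    else:
        force = None
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise TrajectoryParseError(f"{path}: time base is not strictly increasing")
    try:
        return Trajectory(
            t,
            df["extension_nm"].to_numpy(),
            force,
            metadata.pop("trap_separation_nm", None),
            metadata,
        )
    except ValueError as err:
        raise TrajectoryParseError(f"{path}: {err}") from err


def write_trajectories_h5(trajectories: dict[str, Trajectory], path: str | Path) -> None:
    """Write records as HDF5 groups ``/records/<id>/{time,extension,force}``."""
    with h5py.File(path, "w") as f:
        root = f.create_group("records")
        for rec_id, traj in trajectories.items():
            g = root.create_group(str(rec_id))
            g.create_dataset("time", data=traj.time_s)
            g.create_dataset("extension", data=traj.extension_nm)
            if traj.force_pn is not None:
                g.create_dataset("force", data=traj.force_pn)
            if traj.trap_separation_nm is not None:
                g.attrs["trap_separation_nm"] = float(traj.trap_separation_nm)
            for k, v in _scalar_metadata(traj.metadata).items():
                g.attrs[k] = v


def read_trajectories_h5(path: str | Path) -> dict[str, Trajectory]:
    """Read every record group of an HDF5 trajectory file."""
    out: dict[str, Trajectory] = {}
    with h5py.File(path, "r") as f:
        if "records" not in f:
            raise TrajectoryParseError(f"{path}: no /records group")
        for rec_id, g in f["records"].items():
            meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in g.attrs.items()}
            sep = meta.pop("trap_separation_nm", None)
            force = g["force"][()] if "force" in g else None
            out[rec_id] = Trajectory(g["time"][()], g["extension"][()], force, sep, meta)
    return out


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses/arrays/NumPy scalars to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON dump: sorted keys, stable float formatting."""
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
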