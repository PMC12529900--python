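"""Readers and writers for the pipeline's tabular formats.

All tables are plain CSV/TSV with headers (separator chosen by file
extension: ``.tsv``/``.tab`` is tab-separated, anything else comma).  The
data objects are small — 11 steps, at most a few dozen classes, 36-bin
grids — so no binary formats are used.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .averaging import ObservableSet
from .classify import FrameAssignment, TrajectoryTable
from .conformers import TORSION_NAMES
from .ensembles import PopulationTable

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_weights",
    "write_weights",
    "read_experimental",
    "write_observables",
    "read_observables",
    "write_assignments",
]

_TRAJ_COLUMNS = ["step_id", "frame", *TORSION_NAMES]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_trajectory(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> TrajectoryTable:
    """Read a long-format torsion table: one row per (step, frame).

    Expected columns ``step_id, frame`` plus the nine torsions in degrees.
    ``column_map`` renames nonstandard headers (e.g. from MD dihedral
    extraction tools) onto the canonical names, as
    ``{file_column: canonical_name}``.  Torsions are normalized onto
    [0, 360); step order follows first appearance, frames are sorted by
    their frame index.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory {path}: unresolvable column(s) {missing}")
    for col in TORSION_NAMES:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValueError(
                f"trajectory {path}: invalid torsion {col} at step "
                f"{row['step_id']}, frame {row['frame']}"
            )
        df[col] = vals
    steps = list(dict.fromkeys(df["step_id"]))
    frames = {}
    for s in steps:
        sub = df[df["step_id"] == s].sort_values("frame")
        frames[s] = sub[list(TORSION_NAMES)].to_numpy(dtype=float)
    return TrajectoryTable(steps=steps, frames=frames)


def write_trajectory(traj: TrajectoryTable, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for s in traj.steps:
        arr = traj.frames[s]
        for f in range(arr.shape[0]):
            rows.append([s, f, *arr[f]])
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.8f"
    )


def write_assignments(
    assignments: Mapping[str, Sequence[FrameAssignment]], path: str | Path
) -> None:
    path = Path(path)
    rows = [
        {
            "step_id": a.step_id,
            "frame": a.frame_index,
            "class_id": a.class_id if a.class_id is not None else "",
            "distance_sq": a.distance_sq,
        }
        for frames in assignments.values()
        for a in frames
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def write_weights(
    weights: Mapping[str, PopulationTable], path: str | Path
) -> None:
    """Write per-step populations as ``step_id,class_id,weight,n_class,n_frames``."""
    path = Path(path)
    rows = []
    for step, pop in weights.items():
        for cid in sorted(pop.weights):
            rows.append(
                {
                    "step_id": step,
                    "class_id": cid,
                    "weight": pop.weights[cid],
                    "n_class": (pop.n_class or {}).get(cid, ""),
                    "n_frames": pop.n_frames if pop.n_frames is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.12g"
    )


def read_weights(path: str | Path) -> dict[str, PopulationTable]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("step_id", "class_id", "weight"):
        if col not in df.columns:
            raise ValueError(f"weights table {path}: missing column {col}")
    out: dict[str, PopulationTable] = {}
    has_counts = "n_class" in df.columns and df["n_class"].notna().all()
    for step, sub in df.groupby("step_id", sort=False):
        if has_counts:
            out[step] = PopulationTable.from_counts(
                step, dict(zip(sub["class_id"], sub["n_class"].astype(int)))
            )
        else:
            out[step] = PopulationTable(
                step_id=step, weights=dict(zip(sub["class_id"], sub["weight"]))
            )
    return out


def read_experimental(path: str | Path) -> pd.DataFrame:
    """Read a measured-observable table.

    Needs ``step_id`` plus at least one of ``delta`` (internally
    referenced, ppm), ``delta_prime`` (externally referenced, ppm) or
    ``j_exp`` (Hz); ``temperature`` is optional.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "step_id" not in df.columns:
        raise ValueError(f"experimental table {path}: missing step_id")
    if not ({"delta", "delta_prime", "j_exp"} & set(df.columns)):
        raise ValueError(
            f"experimental table {path}: needs delta, delta_prime or j_exp"
        )
    return df


def write_observables(
    observables: Sequence[ObservableSet], path: str | Path
) -> None:
    path = Path(path)
    rows = [
        {
            "step_id": o.step_id,
            "sigma_ppm": o.sigma,
            "delta_ppm": o.delta if o.delta is not None else "",
            "j_hz": o.j_coupling,
            "temperature": o.temperature if o.temperature is not None else "",
        }
        for o in observables
    ]
    pd.DataFrame(rows).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.6f"
    )


def read_observables(path: str | Path) -> list[ObservableSet]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    out = []
    for _, row in df.iterrows():
        delta = row.get("delta_ppm")
        temp = row.get("temperature")
        out.append(
            ObservableSet(
                step_id=row["step_id"],
                sigma=float(row["sigma_ppm"]),
                j_coupling=float(row["j_hz"]),
                delta=float(delta) if pd.notna(delta) else None,
                temperature=float(temp) if pd.notna(temp) else None,
            )
        )
    return out
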