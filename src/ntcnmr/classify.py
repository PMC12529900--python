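"""Assignment of backbone torsion snapshots to NtC classes.

Each trajectory frame of a dinucleotide step is assigned to the nearest
class in nine-dimensional torsion space, where "nearest" minimizes the sum
of squared minimal-arc (circular) differences over the nine torsions.
Because the argmin is invariant under monotone transforms, the squared sum
ranks classes identically to the torsion-space RMSD.  Ties are broken by
lexicographically smallest class identifier so that assignment is
deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conformers import ClassTable, TorsionVector, TORSION_NAMES, normalize_angle

__all__ = [
    "FrameAssignment",
    "TrajectoryTable",
    "circular_diff",
    "torsion_distance_sq",
    "classify_frame",
    "classify_trajectory",
]


@dataclasses.dataclass(frozen=True)
class FrameAssignment:
    """Nearest-class assignment of one frame of one step.

    ``class_id`` is ``None`` only when an optional distance cutoff was
    requested and the frame lies beyond it.
    """

    frame_index: int
    step_id: str
    class_id: str | None
    distance_sq: float


@dataclasses.dataclass
class TrajectoryTable:
    """Per-step torsion time series.

    ``frames`` maps each step label to an (N, 9) array of torsions in
    degrees, columns ordered as :data:`~ntcnmr.conformers.TORSION_NAMES`;
    all steps must hold the same number of frames.
    """

    steps: list[str]
    frames: dict[str, np.ndarray]
    temperature: float | None = None
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("trajectory has no steps")
        counts = set()
        for s in self.steps:
            if s not in self.frames:
                raise ValueError(f"step {s} has no frames")
            arr = np.asarray(self.frames[s], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(TORSION_NAMES):
                raise ValueError(
                    f"step {s}: expected (N, {len(TORSION_NAMES)}) torsions, "
                    f"got shape {arr.shape}"
                )
            if arr.shape[0] < 1:
                raise ValueError(f"step {s} has zero frames")
            bad = np.argwhere(~np.isfinite(arr))
            if len(bad):
                f, t = bad[0]
                raise ValueError(
                    f"step {s}, frame {f}: torsion {TORSION_NAMES[t]} is not finite"
                )
            self.frames[s] = normalize_angle(arr)
            counts.add(arr.shape[0])
        if len(counts) > 1:
            raise ValueError(f"steps have unequal frame counts: {sorted(counts)}")

    @property
    def n_frames(self) -> int:
        return self.frames[self.steps[0]].shape[0]


def circular_diff(a, b):
    """Signed minimal-arc difference a - b in (-180, 180], degrees.

    Accepts scalars or arrays (broadcast).
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d


def torsion_distance_sq(t_a: TorsionVector, t_b: TorsionVector) -> float:
    """Squared circular distance between two torsion vectors, deg^2."""
    d = circular_diff(t_a.as_array(), t_b.as_array())
    return float(np.sum(d * d))


def _distance_matrix(frames: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(N, n_classes) squared circular distances."""
    d = (frames[:, None, :] - centers[None, :, :]) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return np.einsum("nct,nct->nc", d, d)


def classify_frame(t: TorsionVector, table: ClassTable) -> FrameAssignment:
    """Assign a single torsion vector to its nearest NtC class."""
    if len(table) == 0:
        raise ValueError("cannot classify against an empty class table")
    ids = sorted(table.ids)
    centers = table.torsion_matrix(order=ids)
    dist = _distance_matrix(t.as_array()[None, :], centers)[0]
    k = int(np.argmin(dist))  # first minimum -> lexicographically smallest id
    return FrameAssignment(
        frame_index=0, step_id="", class_id=ids[k], distance_sq=float(dist[k])
    )


def classify_trajectory(
    traj: TrajectoryTable,
    table: ClassTable,
    cutoff: float | None = None,
) -> dict[str, list[FrameAssignment]]:
    """Assign every frame of every step to its nearest class.

    Parameters
    ----------
    cutoff
        Optional squared-distance threshold (deg^2).  Frames whose minimal
        distance exceeds it are returned with ``class_id=None`` instead of
        being force-assigned.  Off by default: every frame is assigned to
        its nearest class.
    """
    ids = sorted(table.ids)
    centers = table.torsion_matrix(order=ids)
    out: dict[str, list[FrameAssignment]] = {}
    for step in traj.steps:
        dist = _distance_matrix(traj.frames[step], centers)
        kmin = np.argmin(dist, axis=1)
        dmin = dist[np.arange(len(kmin)), kmin]
        assignments = []
        for f, (k, d) in enumerate(zip(kmin, dmin)):
            cid: str | None = ids[int(k)]
            if cutoff is not None and d > cutoff:
                cid = None
            assignments.append(
                FrameAssignment(
                    frame_index=f, step_id=step, class_id=cid, distance_sq=float(d)
                )
            )
        out[step] = assignments
    return out
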