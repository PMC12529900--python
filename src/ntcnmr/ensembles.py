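"""Ensemble statistics over NtC-classified trajectories.

Population weights of a step are the relative occurrences of each NtC
class among its N classified frames, w = N_class / N, which sum to one by
construction.  Class-conditional torsion distributions are discretized on
a fixed 10-degree grid of 36 half-open bins [10(k-1), 10k) covering
[0, 360); no smoothing or kernel density estimation is applied.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .classify import FrameAssignment, TrajectoryTable
from .conformers import BIN_WIDTH, N_BINS, TORSION_NAMES, torsion_bin

__all__ = [
    "PopulationTable",
    "TorsionHistogram",
    "JointHistogram",
    "population_weights",
    "torsion_histogram",
    "joint_histogram",
]


@dataclasses.dataclass
class PopulationTable:
    """Per-step NtC population weights, optionally backed by frame counts.

    Count-derived tables (from classified trajectories) store the exact
    integer counts alongside the derived fractions w = N_class / N, which
    then sum to 1 up to one floating division per class.  Fitted or
    externally supplied tables may carry fractional weights only.
    """

    step_id: str
    weights: dict[str, float]
    n_frames: int | None = None
    n_class: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.weights = {c: float(w) for c, w in self.weights.items() if w != 0}
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"step {self.step_id}: negative population weight")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"step {self.step_id}: weights sum to {total!r}, expected 1"
            )
        if self.n_class is not None:
            if self.n_frames != sum(self.n_class.values()):
                raise ValueError(
                    f"step {self.step_id}: class counts do not sum to n_frames"
                )
            for c, n in self.n_class.items():
                if n > 0 and self.weights.get(c) != n / self.n_frames:
                    raise ValueError(
                        f"step {self.step_id}: weight of {c} is not N_class/N"
                    )

    def weight(self, class_id: str) -> float:
        return self.weights.get(class_id, 0.0)

    @classmethod
    def from_counts(
        cls, step_id: str, n_class: Mapping[str, int]
    ) -> "PopulationTable":
        n = sum(n_class.values())
        if n < 1:
            raise ValueError(f"step {step_id}: zero frames")
        return cls(
            step_id=step_id,
            weights={c: k / n for c, k in n_class.items() if k > 0},
            n_frames=n,
            n_class={c: int(k) for c, k in n_class.items() if k > 0},
        )


@dataclasses.dataclass
class TorsionHistogram:
    """36-bin class-conditional probability distribution of one torsion."""

    class_id: str
    torsion_name: str
    bins: np.ndarray
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.bins.shape}")
        if np.any(self.bins < 0):
            raise ValueError("negative bin probability")
        if self.n_frames > 0 and abs(self.bins.sum() - 1.0) > 1e-12:
            raise ValueError(f"bins sum to {self.bins.sum()!r}, expected 1")

    @property
    def is_empty(self) -> bool:
        return self.n_frames == 0

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(N_BINS + 1) * BIN_WIDTH


@dataclasses.dataclass
class JointHistogram:
    """36x36 class-conditional joint distribution over (alpha, zeta)."""

    class_id: str
    grid: np.ndarray
    torsion_pair: tuple[str, str] = ("alpha3", "zeta")
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (N_BINS, N_BINS):
            raise ValueError(f"expected {N_BINS}x{N_BINS} grid, got {self.grid.shape}")
        if np.any(self.grid < 0):
            raise ValueError("negative bin probability")
        if self.n_frames > 0 and abs(self.grid.sum() - 1.0) > 1e-12:
            raise ValueError(f"grid sums to {self.grid.sum()!r}, expected 1")

    @property
    def is_empty(self) -> bool:
        return self.n_frames == 0

    def marginal(self, axis_name: str) -> TorsionHistogram:
        """Marginal distribution over one member of the torsion pair."""
        if axis_name == self.torsion_pair[0]:
            bins = self.grid.sum(axis=1)
        elif axis_name == self.torsion_pair[1]:
            bins = self.grid.sum(axis=0)
        else:
            raise ValueError(f"{axis_name} not in pair {self.torsion_pair}")
        if self.n_frames > 0:
            bins = bins / bins.sum()
        return TorsionHistogram(
            class_id=self.class_id,
            torsion_name=axis_name,
            bins=bins,
            n_frames=self.n_frames,
        )


def population_weights(
    assignments: Mapping[str, Sequence[FrameAssignment]],
) -> dict[str, PopulationTable]:
    """Count class occurrences per step into population tables.

    Frames left unassigned by a distance cutoff are excluded from both the
    numerator and the denominator.
    """
    out: dict[str, PopulationTable] = {}
    for step, frames in assignments.items():
        counts: dict[str, int] = {}
        n = 0
        for a in frames:
            if a.class_id is None:
                continue
            counts[a.class_id] = counts.get(a.class_id, 0) + 1
            n += 1
        if n == 0:
            raise ValueError(f"step {step}: no classified frames")
        out[step] = PopulationTable.from_counts(step, counts)
    return out


def _class_frames(
    traj: TrajectoryTable,
    assignments: Mapping[str, Sequence[FrameAssignment]],
    step_id: str,
    class_id: str,
) -> np.ndarray:
    mask = np.array(
        [a.class_id == class_id for a in assignments[step_id]], dtype=bool
    )
    return traj.frames[step_id][mask]


def torsion_histogram(
    traj: TrajectoryTable,
    assignments: Mapping[str, Sequence[FrameAssignment]],
    step_id: str,
    class_id: str,
    torsion_name: str,
) -> TorsionHistogram:
    """Histogram of one torsion over the frames of a step assigned to a class.

    A class with zero assigned frames yields an empty histogram
    (``is_empty``), not an error.
    """
    if torsion_name not in TORSION_NAMES:
        raise ValueError(f"unknown torsion {torsion_name!r}")
    frames = _class_frames(traj, assignments, step_id, class_id)
    col = TORSION_NAMES.index(torsion_name)
    counts = np.bincount(torsion_bin(frames[:, col]), minlength=N_BINS).astype(float)
    n = frames.shape[0]
    return TorsionHistogram(
        class_id=class_id,
        torsion_name=torsion_name,
        bins=counts / n if n else counts,
        n_frames=n,
    )


def joint_histogram(
    traj: TrajectoryTable,
    assignments: Mapping[str, Sequence[FrameAssignment]],
    step_id: str,
    class_id: str,
    torsion_pair: tuple[str, str] = ("alpha3", "zeta"),
) -> JointHistogram:
    """Joint 36x36 histogram over a torsion pair (default alpha x zeta,
    the two torsions flanking the step's phosphate)."""
    frames = _class_frames(traj, assignments, step_id, class_id)
    ia = TORSION_NAMES.index(torsion_pair[0])
    iz = TORSION_NAMES.index(torsion_pair[1])
    ka = torsion_bin(frames[:, ia])
    kz = torsion_bin(frames[:, iz])
    grid = np.zeros((N_BINS, N_BINS))
    np.add.at(grid, (ka, kz), 1.0)
    n = frames.shape[0]
    return JointHistogram(
        class_id=class_id,
        grid=grid / n if n else grid,
        torsion_pair=torsion_pair,
        n_frames=n,
    )
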