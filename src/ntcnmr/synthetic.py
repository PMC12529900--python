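"""Synthetic generators for every input the pipeline consumes.

Real inputs of this analysis are (i) an NtC class table with QM-derived
phosphate NMR parameters, (ii) torsion trajectories extracted from
microsecond MD of a DNA duplex, and (iii) measured per-phosphate
delta-31P and 3J(P,H3') tables.  The generators here emulate all three so
that every stage of the pipeline is testable end to end without any
external data:

* trajectories are drawn from per-step NtC mixtures with independent
  wrapped-Gaussian torsion noise around the class-defining centers;
* class parameter dependences are filled with a Karplus-type coupling
  curve over epsilon and a smooth low-order periodic shielding surface
  over (alpha, zeta), both anchored so the value at the class-defining
  bin equals the class scalar;
* experimental tables are forward-computed from known populations with
  additive Gaussian noise, internally referenced by construction.

The default duplex mimics the Dickerson-Drew dodecamer
5'-CGCGAATTCGCG-3': 11 phosphate steps, BI-dominated in the central stem
and with elevated BII-family populations toward the termini.  All
generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .averaging import REFERENCE_STEP, population_average, reference_delta
from .classify import TrajectoryTable
from .conformers import (
    BIN_WIDTH,
    ClassTable,
    N_BINS,
    NtCClass,
    TORSION_NAMES,
    normalize_angle,
)
from .ensembles import PopulationTable

__all__ = [
    "DDD_STEPS",
    "MixtureSpec",
    "DuplexSpec",
    "default_duplex_spec",
    "sample_trajectory",
    "synthetic_dependences",
    "synthetic_experiment",
]

#: The 11 internucleotide steps of the Dickerson-Drew dodecamer, 5' to 3'.
DDD_STEPS: tuple[str, ...] = (
    "C1pG2",
    "G2pC3",
    "C3pG4",
    "G4pA5",
    "A5pA6",
    "A6pT7",
    "T7pT8",
    "T8pC9",
    "C9pG10",
    "G10pC11",
    "C11pG12",
)

#: Synthetic Karplus coefficients (Hz) for the 3J(P,H3') epsilon curve,
#: J = A cos^2(theta) + B cos(theta) + C.  Arbitrary-but-fixed values in
#: the range typical of three-bond P-H couplings; they make no claim of
#: matching any QM-derived parametrization.
DEFAULT_KARPLUS: tuple[float, float, float] = (15.3, -6.2, 1.5)


@dataclasses.dataclass
class MixtureSpec:
    """NtC mixture generating one step's frames."""

    step_id: str
    target_weights: dict[str, float]
    torsion_noise_sd: float = 8.0
    n_frames: int = 2000

    def __post_init__(self) -> None:
        total = sum(self.target_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"step {self.step_id}: target weights sum to {total!r}"
            )
        if any(w < 0 for w in self.target_weights.values()):
            raise ValueError(f"step {self.step_id}: negative target weight")
        if self.n_frames < 1:
            raise ValueError(f"step {self.step_id}: n_frames must be >= 1")
        if self.torsion_noise_sd < 0:
            raise ValueError(f"step {self.step_id}: negative noise sd")


@dataclasses.dataclass
class DuplexSpec:
    """Ordered per-step mixtures of one duplex at one temperature."""

    mixtures: list[MixtureSpec]
    temperature: float | None = 20.0

    def __post_init__(self) -> None:
        ids = [m.step_id for m in self.mixtures]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate step labels in duplex spec")

    @property
    def steps(self) -> list[str]:
        return [m.step_id for m in self.mixtures]


# Per-step mixtures of the default duplex.  Stem steps are BI-dominated;
# tail and junction steps carry elevated BII-family (BB04/BB07) and
# residual populations, echoing the qualitative stem/tail contrast seen
# in B-DNA simulations of this dodecamer.
_DEFAULT_MIXTURES: Mapping[str, Mapping[str, float]] = {
    "C1pG2": {"BB00": 0.28, "BB01": 0.12, "BB04": 0.18, "BB07": 0.22, "BA01": 0.10, "OT01": 0.10},
    "G2pC3": {"BB00": 0.52, "BB01": 0.18, "BB04": 0.10, "BB07": 0.08, "BA05": 0.12},
    "C3pG4": {"BB00": 0.45, "BB01": 0.15, "BB04": 0.14, "BB07": 0.14, "AB01": 0.12},
    "G4pA5": {"BB00": 0.34, "BB01": 0.12, "BB04": 0.20, "BB07": 0.24, "BA01": 0.10},
    "A5pA6": {"BB00": 0.62, "BB01": 0.20, "BB04": 0.08, "BB07": 0.04, "BA05": 0.06},
    "A6pT7": {"BB00": 0.70, "BB01": 0.18, "BB04": 0.06, "BB07": 0.03, "BA05": 0.03},
    "T7pT8": {"BB00": 0.66, "BB01": 0.20, "BB04": 0.07, "BB07": 0.04, "AB01": 0.03},
    "T8pC9": {"BB00": 0.60, "BB01": 0.22, "BB04": 0.08, "BB07": 0.05, "BA05": 0.05},
    "C9pG10": {"BB00": 0.36, "BB01": 0.12, "BB04": 0.18, "BB07": 0.22, "OT01": 0.12},
    "G10pC11": {"BB00": 0.38, "BB01": 0.14, "BB04": 0.16, "BB07": 0.20, "BA01": 0.12},
    "C11pG12": {"BB00": 0.30, "BB01": 0.12, "BB04": 0.18, "BB07": 0.24, "OT01": 0.16},
}


def default_duplex_spec(
    n_frames: int = 2000,
    torsion_noise_sd: float = 8.0,
    temperature: float = 20.0,
) -> DuplexSpec:
    """The default 11-step Dickerson-Drew-like duplex specification."""
    return DuplexSpec(
        mixtures=[
            MixtureSpec(
                step_id=s,
                target_weights=dict(_DEFAULT_MIXTURES[s]),
                torsion_noise_sd=torsion_noise_sd,
                n_frames=n_frames,
            )
            for s in DDD_STEPS
        ],
        temperature=temperature,
    )


def sample_trajectory(
    spec: DuplexSpec, table: ClassTable, seed: int
) -> tuple[TrajectoryTable, dict[str, np.ndarray]]:
    """Draw a torsion trajectory from per-step NtC mixtures.

    Each frame picks a class from the step's target weights and adds
    independent wrapped-Gaussian noise (the stated sd, wrapped onto
    [0, 360)) to each of the nine class-defining torsions.  Returns the
    trajectory plus the ground-truth class label of every frame.
    """
    for m in spec.mixtures:
        unknown = sorted(set(m.target_weights) - set(table.ids))
        if unknown:
            raise ValueError(f"step {m.step_id}: unknown class id(s) {unknown}")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(spec.mixtures))
    frames: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for m, ss in zip(spec.mixtures, streams):
        rng = np.random.default_rng(ss)
        ids = sorted(m.target_weights)
        probs = np.array([m.target_weights[c] for c in ids])
        picks = rng.choice(len(ids), size=m.n_frames, p=probs / probs.sum())
        centers = table.torsion_matrix(order=ids)
        noise = rng.normal(0.0, m.torsion_noise_sd, size=(m.n_frames, len(TORSION_NAMES))) \
            if m.torsion_noise_sd > 0 else np.zeros((m.n_frames, len(TORSION_NAMES)))
        frames[m.step_id] = normalize_angle(centers[picks] + noise)
        labels[m.step_id] = np.array([ids[k] for k in picks])
    traj = TrajectoryTable(
        steps=list(spec.steps),
        frames=frames,
        temperature=spec.temperature,
        frame_interval_ps=10.0,
    )
    return traj, labels


def _bin_centers() -> np.ndarray:
    return (np.arange(N_BINS) + 0.5) * BIN_WIDTH


def karplus_curve(
    coefficients: tuple[float, float, float] = DEFAULT_KARPLUS,
    angles_deg: np.ndarray | None = None,
) -> np.ndarray:
    """Karplus-type curve A cos^2 + B cos + C at given angles (degrees)."""
    a, b, c = coefficients
    theta = np.deg2rad(_bin_centers() if angles_deg is None else np.asarray(angles_deg))
    ct = np.cos(theta)
    return a * ct * ct + b * ct + c


def synthetic_dependences(
    table: ClassTable,
    karplus: tuple[float, float, float] = DEFAULT_KARPLUS,
    seed: int = 0,
    surface_amplitude: float = 1.5,
) -> ClassTable:
    """Fill sigma_surface and j_curve for every class of a table.

    The coupling curve is the Karplus form evaluated at the 36 epsilon bin
    centers; the shielding surface is a smooth first-harmonic periodic
    function of (alpha, zeta) with seeded phases and the stated amplitude
    (ppm).  Both are shifted per class so that their value at the bin
    containing the class-defining torsions equals the class scalar, which
    keeps probability averaging consistent with population averaging in
    the zero-width limit.
    """
    rng = np.random.default_rng(seed)
    centers = np.deg2rad(_bin_centers())
    base_curve = karplus_curve(karplus)
    new_classes = []
    for cls in table:
        ka, kz, ke = cls.center_bins
        phase_a, phase_z = rng.uniform(0.0, 2.0 * math.pi, size=2)
        alpha_grid = np.cos(centers - phase_a)[:, None]
        zeta_grid = np.cos(centers - phase_z)[None, :]
        cross = 0.3 * alpha_grid * zeta_grid
        surface = surface_amplitude * (alpha_grid + zeta_grid + cross)
        surface = surface + (cls.sigma - surface[ka, kz])
        curve = base_curve + (cls.j_coupling - base_curve[ke])
        new_classes.append(
            dataclasses.replace(
                cls, sigma_surface=surface, j_curve=curve
            )
        )
    return ClassTable(classes=new_classes, source=table.source + "+dependences")


def synthetic_experiment(
    true_weights: Mapping[str, PopulationTable],
    table: ClassTable,
    noise_delta: float = 0.0,
    noise_j: float = 0.0,
    seed: int = 0,
    reference_step: str = REFERENCE_STEP,
    temperature: float | None = 20.0,
) -> pd.DataFrame:
    """Forward-generate a measured-observable table from known populations.

    Observables are population-weighted averages referenced to the chosen
    internal standard; independent Gaussian noise (sd in ppm / Hz) is then
    added per step and observable.  The reference step's delta is re-zeroed
    after noising — internal referencing is exact by definition.  Columns:
    ``step_id, delta, j_exp, temperature``.
    """
    if reference_step not in true_weights:
        raise ValueError(f"reference step {reference_step} not in weights")
    rng = np.random.default_rng(seed)
    obs = [population_average(w, table) for w in true_weights.values()]
    obs = reference_delta(obs, reference_step)
    rows = []
    for o in obs:
        delta = o.delta + (rng.normal(0.0, noise_delta) if noise_delta > 0 else 0.0)
        j = o.j_coupling + (rng.normal(0.0, noise_j) if noise_j > 0 else 0.0)
        if o.step_id == reference_step:
            delta = 0.0
        rows.append(
            {
                "step_id": o.step_id,
                "delta": delta,
                "j_exp": j,
                "temperature": temperature,
            }
        )
    return pd.DataFrame(rows)
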