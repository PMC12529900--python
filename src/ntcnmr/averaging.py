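"""Ensemble averaging of phosphate NMR parameters and internal referencing.

Two averaging schemes are provided.  *Population weighting* forms

    sigma = sum_i w_i * sigma_i        J = sum_i w_i * J_i

over NtC classes i with population weights w_i and class-specific scalar
parameters.  *Probability averaging* refines the scalars of the BI-family
(BB00, BB01) and BII-family (BB04, BB07) classes by the expectation of the
class's discretized parameter dependence under the class-conditional
torsion distribution: the shielding surface sigma_i(alpha_k, zeta_j) under
the joint (alpha, zeta) histogram and the coupling curve J_i(epsilon_k)
under the epsilon histogram, both piecewise-constant on 10-degree bins.
Classes outside those families always contribute their scalars.

Chemical shifts are referenced internally to a chosen step (A6pT7 by
convention for the Dickerson-Drew dodecamer): computed shifts as
delta = sigma(ref) - sigma, measured shifts as delta = delta' - delta'(ref)
where delta' is the shift against an external standard.  The reference
step's delta is exactly zero in both conventions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .conformers import ClassTable
from .ensembles import JointHistogram, PopulationTable, TorsionHistogram

__all__ = [
    "REFERENCE_STEP",
    "ObservableSet",
    "ClassHistograms",
    "population_average",
    "probability_average",
    "reference_delta",
    "rereference_experimental",
]

#: Default internal reference phosphate of the Dickerson-Drew dodecamer.
REFERENCE_STEP = "A6pT7"


@dataclasses.dataclass
class ObservableSet:
    """Averaged NMR observables of one step's phosphate."""

    step_id: str
    sigma: float
    j_coupling: float
    delta: float | None = None
    temperature: float | None = None


@dataclasses.dataclass
class ClassHistograms:
    """Class-conditional torsion distributions needed for probability
    averaging: the joint (alpha, zeta) histogram for the shielding surface
    and the epsilon histogram for the coupling curve."""

    joint_alpha_zeta: JointHistogram
    epsilon: TorsionHistogram


def population_average(
    weights: PopulationTable, table: ClassTable
) -> ObservableSet:
    """Population-weighted scalar averages of sigma and J for one step."""
    sigma = 0.0
    j = 0.0
    for cid, w in weights.weights.items():
        try:
            cls = table[cid]
        except KeyError:
            raise KeyError(
                f"step {weights.step_id}: class {cid} (w={w:.4g}) missing "
                "from the class table"
            ) from None
        sigma += w * cls.sigma
        j += w * cls.j_coupling
    return ObservableSet(step_id=weights.step_id, sigma=sigma, j_coupling=j)


def probability_average(
    weights: PopulationTable,
    histograms: Mapping[str, ClassHistograms],
    table: ClassTable,
    product_marginals: bool = False,
) -> ObservableSet:
    """Probability-averaged sigma and J for one step.

    Classes in the BI/BII families must supply histograms (via
    ``histograms``) plus a sigma_surface and j_curve in the class table;
    any other populated class contributes its scalar parameters.  With
    ``product_marginals`` the joint (alpha, zeta) distribution is replaced
    by the outer product of its marginals.
    """
    sigma = 0.0
    j = 0.0
    for cid, w in weights.weights.items():
        cls = table[cid]
        if cls.family not in ("BI_family", "BII_family"):
            sigma += w * cls.sigma
            j += w * cls.j_coupling
            continue
        if cls.sigma_surface is None or cls.j_curve is None:
            raise ValueError(
                f"step {weights.step_id}: family class {cid} lacks "
                "sigma_surface/j_curve needed for probability averaging"
            )
        if cid not in histograms:
            raise ValueError(
                f"step {weights.step_id}: no histograms supplied for class {cid}"
            )
        h = histograms[cid]
        if h.joint_alpha_zeta.is_empty or h.epsilon.is_empty:
            # class populated in weights but histogram empty: inconsistent input
            raise ValueError(
                f"step {weights.step_id}: empty histogram for populated class {cid}"
            )
        grid = h.joint_alpha_zeta.grid
        if product_marginals:
            grid = np.outer(
                h.joint_alpha_zeta.marginal("alpha3").bins,
                h.joint_alpha_zeta.marginal("zeta").bins,
            )
        if abs(grid.sum() - 1.0) > 1e-9 or abs(h.epsilon.bins.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"step {weights.step_id}: histogram for class {cid} is not normalized"
            )
        sigma += w * float(np.sum(grid * cls.sigma_surface))
        j += w * float(np.dot(h.epsilon.bins, cls.j_curve))
    return ObservableSet(step_id=weights.step_id, sigma=sigma, j_coupling=j)


def reference_delta(
    observables: Iterable[ObservableSet],
    reference_step: str = REFERENCE_STEP,
) -> list[ObservableSet]:
    """Set delta = sigma(reference) - sigma for every step.

    Larger shielding therefore means a smaller (more upfield) shift, and
    the reference step's delta is exactly zero.
    """
    obs = list(observables)
    ref = [o for o in obs if o.step_id == reference_step]
    if not ref:
        raise ValueError(f"reference step {reference_step} not present")
    sigma_ref = ref[0].sigma
    return [
        dataclasses.replace(o, delta=0.0 if o.step_id == reference_step
                            else sigma_ref - o.sigma)
        for o in obs
    ]


def rereference_experimental(
    exp: pd.DataFrame, reference_step: str = REFERENCE_STEP
) -> pd.DataFrame:
    """Re-reference measured shifts to an internal standard step.

    ``exp`` must carry ``step_id`` and ``delta_prime`` (shift against the
    external standard, ppm); the returned copy gains/overwrites ``delta``
    with delta' - delta'(reference).  Idempotent: re-referencing an already
    referenced table (where delta'(ref) = 0) changes nothing.  Rows are
    re-referenced within each temperature when a ``temperature`` column is
    present.
    """
    if "delta_prime" not in exp.columns:
        raise ValueError("experimental table lacks a delta_prime column")
    out = exp.copy()

    def _ref_group(g: pd.DataFrame) -> pd.DataFrame:
        ref = g.loc[g["step_id"] == reference_step, "delta_prime"]
        if ref.empty:
            raise ValueError(f"reference step {reference_step} not present")
        g = g.copy()
        g["delta"] = g["delta_prime"] - float(ref.iloc[0])
        return g

    if "temperature" in out.columns and out["temperature"].notna().any():
        parts = [
            _ref_group(g) for _, g in out.groupby("temperature", dropna=False)
        ]
        out = pd.concat(parts).sort_index()
    else:
        out = _ref_group(out)
    return out
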