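"""Agreement scoring and BI'/BII' population fitting.

Accuracy of calculated observables against experiment is scored with a
root-mean-square deviation over steps,

    MAD = sqrt( (1/N) * sum_i (X_calc,i - X_exp,i)^2 ),   X in {J, delta},

historically labelled "mean absolute deviation" in parts of the ³¹P NMR
literature; the RMS form is what reproduces the published per-table
values, and it is the form implemented here (see the methods note).

Population fitting adjusts, per phosphate, the split of the combined
BI' = {BB00, BB01} and BII' = {BB04, BB07} population pool so that the
population-weighted observable matches an experimental target.  The
within-group class ratios are held fixed at their input (simulation)
values, populations of classes outside the pool are untouched, and the
observable is affine in the BII' fraction x, so each step reduces to a
scalar linear solve, clamped to the physical range [0, 1].  The standard
two-stage protocol fits x to the measured ³J couplings first — which also
refreshes the shielding of the internal reference step — and then refits
against the re-referenced chemical shifts.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .averaging import ObservableSet, REFERENCE_STEP, population_average
from .conformers import ClassTable
from .ensembles import PopulationTable

__all__ = [
    "AccuracyReport",
    "FitGroups",
    "FitResult",
    "mad",
    "forward_observables",
    "fit_step_population",
    "fit_equilibrium",
]


@dataclasses.dataclass
class AccuracyReport:
    """Per-step deviations (calc - exp) and their RMS summary."""

    observable: str
    per_step_dev: dict[str, float]
    mad: float


def mad(
    calc: Mapping[str, float],
    exp: Mapping[str, float],
    observable: str = "delta",
) -> AccuracyReport:
    """Root-mean-square deviation between paired per-step values.

    The step sets must match exactly; the mismatch is reported otherwise.
    """
    calc_steps, exp_steps = set(calc), set(exp)
    if calc_steps != exp_steps:
        only_calc = sorted(calc_steps - exp_steps)
        only_exp = sorted(exp_steps - calc_steps)
        raise ValueError(
            f"step sets differ: only in calc {only_calc}, only in exp {only_exp}"
        )
    dev = {s: float(calc[s]) - float(exp[s]) for s in sorted(calc_steps)}
    rms = float(np.sqrt(np.mean(np.square(list(dev.values())))))
    return AccuracyReport(observable=observable, per_step_dev=dev, mad=rms)


@dataclasses.dataclass
class FitGroups:
    """The BI'/BII' grouping with fixed within-group population ratios."""

    bi_prime: frozenset[str] = frozenset({"BB00", "BB01"})
    bii_prime: frozenset[str] = frozenset({"BB04", "BB07"})
    intra_ratios: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bi_prime = frozenset(self.bi_prime)
        self.bii_prime = frozenset(self.bii_prime)
        if self.bi_prime & self.bii_prime:
            raise ValueError(
                f"groups overlap: {sorted(self.bi_prime & self.bii_prime)}"
            )
        for group in (self.bi_prime, self.bii_prime):
            ratios = [self.intra_ratios.get(c, 0.0) for c in group]
            if self.intra_ratios and abs(sum(ratios) - 1.0) > 1e-9:
                raise ValueError(
                    f"intra-group ratios of {sorted(group)} sum to {sum(ratios)}"
                )

    @property
    def pool(self) -> frozenset[str]:
        return self.bi_prime | self.bii_prime

    @classmethod
    def from_weights(
        cls,
        weights: PopulationTable,
        bi_prime: Iterable[str] = ("BB00", "BB01"),
        bii_prime: Iterable[str] = ("BB04", "BB07"),
    ) -> "FitGroups":
        """Freeze within-group ratios at a step's simulated populations.

        A group with no population mass falls back to an equal split, so
        the fit can still move mass into it.
        """
        bi, bii = frozenset(bi_prime), frozenset(bii_prime)
        ratios: dict[str, float] = {}
        for group in (bi, bii):
            mass = sum(weights.weight(c) for c in group)
            for c in sorted(group):
                ratios[c] = (
                    weights.weight(c) / mass if mass > 0 else 1.0 / len(group)
                )
        return cls(bi_prime=bi, bii_prime=bii, intra_ratios=ratios)


@dataclasses.dataclass
class FitResult:
    """Fitted BII' fraction and regrouped populations of one step."""

    step_id: str
    x_bii: float
    fitted_weights: PopulationTable
    delta_w: dict[str, float]
    refit_observables: ObservableSet
    clamped: bool = False
    skipped: bool = False
    message: str = ""


def _regrouped_weights(
    x_bii: float, weights: PopulationTable, groups: FitGroups
) -> dict[str, float]:
    w = dict(weights.weights)
    pool_mass = sum(w.get(c, 0.0) for c in groups.pool)
    if pool_mass <= 0:
        raise ValueError(
            f"step {weights.step_id}: no population in the BI'/BII' pool"
        )
    for c in groups.pool:
        w.pop(c, None)
    for c in groups.bii_prime:
        val = pool_mass * x_bii * groups.intra_ratios.get(c, 0.0)
        if val > 0:
            w[c] = val
    for c in groups.bi_prime:
        val = pool_mass * (1.0 - x_bii) * groups.intra_ratios.get(c, 0.0)
        if val > 0:
            w[c] = val
    return w


def forward_observables(
    x_bii: float,
    weights: PopulationTable,
    groups: FitGroups,
    table: ClassTable,
) -> ObservableSet:
    """Population-averaged observables after setting the BII' fraction.

    The BI'+BII' pool mass is preserved; x_bii of it goes to the BII'
    classes (split by the fixed intra-group ratios) and the rest to BI'.
    Non-pool class weights are untouched.
    """
    if not 0.0 <= x_bii <= 1.0:
        raise ValueError(f"x_bii must lie in [0, 1], got {x_bii}")
    w = _regrouped_weights(x_bii, weights, groups)
    sigma = 0.0
    j = 0.0
    for cid, wi in w.items():
        cls = table[cid]
        sigma += wi * cls.sigma
        j += wi * cls.j_coupling
    return ObservableSet(step_id=weights.step_id, sigma=sigma, j_coupling=j)


def fit_step_population(
    target: float,
    weights: PopulationTable,
    groups: FitGroups,
    table: ClassTable,
    observable: str = "j",
    reference_sigma: float | None = None,
    degenerate_tol: float = 1e-12,
) -> FitResult:
    """Solve for the BII' fraction matching one experimental value.

    ``observable`` is ``"j"`` (coupling, Hz) or ``"delta"`` (referenced
    shift, ppm; requires ``reference_sigma``, the shielding of the internal
    reference step).  The observable is affine in x, so the fit is an exact
    scalar solve; solutions outside [0, 1] are clamped and flagged.
    """
    groups = (
        groups
        if groups.intra_ratios
        else FitGroups.from_weights(weights, groups.bi_prime, groups.bii_prime)
    )

    def value(x: float) -> float:
        obs = forward_observables(x, weights, groups, table)
        if observable == "j":
            return obs.j_coupling
        if observable == "delta":
            if reference_sigma is None:
                raise ValueError("fitting delta requires reference_sigma")
            return reference_sigma - obs.sigma
        raise ValueError(f"unknown observable {observable!r}")

    v0, v1 = value(0.0), value(1.0)
    slope = v1 - v0
    if abs(slope) <= degenerate_tol:
        raise ValueError(
            f"step {weights.step_id}: BI' and BII' pool observables are "
            f"degenerate for {observable} (both {v0:.6g}); no information to fit"
        )
    x = (float(target) - v0) / slope
    clamped = not (0.0 <= x <= 1.0)
    x = float(min(1.0, max(0.0, x)))
    fitted = PopulationTable(
        step_id=weights.step_id, weights=_regrouped_weights(x, weights, groups)
    )
    all_ids = set(weights.weights) | set(fitted.weights)
    delta_w = {
        c: weights.weights.get(c, 0.0) - fitted.weights.get(c, 0.0)
        for c in sorted(all_ids)
    }
    return FitResult(
        step_id=weights.step_id,
        x_bii=x,
        fitted_weights=fitted,
        delta_w=delta_w,
        refit_observables=forward_observables(x, weights, groups, table),
        clamped=clamped,
    )


def fit_equilibrium(
    exp: pd.DataFrame,
    weights: Mapping[str, PopulationTable],
    table: ClassTable,
    groups: FitGroups | None = None,
    stages: Sequence[str] = ("j", "delta"),
    reference_step: str = REFERENCE_STEP,
) -> tuple[dict[str, FitResult], dict[str, AccuracyReport]]:
    """Two-stage per-step population fit against an experimental table.

    ``exp`` needs columns ``step_id``, ``j_exp`` (Hz) and ``delta`` (ppm,
    internally referenced).  Stage ``"j"`` fits every step's BII' fraction
    to its measured coupling; the reference step's refitted shielding then
    replaces the delta reference.  Stage ``"delta"`` refits the fractions
    against the measured shifts using that refreshed reference.  Steps with
    a degenerate or empty pool are skipped with their input populations
    retained.  Returns per-step results of the final stage plus accuracy
    reports for both observables evaluated at the final populations.
    """
    bad = set(stages) - {"j", "delta"}
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    exp = exp.set_index("step_id") if "step_id" in exp.columns else exp
    step_ids = list(weights)
    missing = sorted(set(step_ids) - set(exp.index))
    if missing:
        raise ValueError(f"experimental table lacks step(s): {missing}")

    base_groups = groups or FitGroups()
    per_step_groups = {
        s: (
            base_groups
            if base_groups.intra_ratios
            else FitGroups.from_weights(
                weights[s], base_groups.bi_prime, base_groups.bii_prime
            )
        )
        for s in step_ids
    }

    current: dict[str, PopulationTable] = dict(weights)
    results: dict[str, FitResult] = {}
    reference_sigma = population_average(current[reference_step], table).sigma \
        if reference_step in current else None

    for stage in stages:
        stage_results: dict[str, FitResult] = {}
        for s in step_ids:
            target = float(
                exp.loc[s, "j_exp" if stage == "j" else "delta"]
            )
            try:
                res = fit_step_population(
                    target,
                    current[s],
                    per_step_groups[s],
                    table,
                    observable=stage,
                    reference_sigma=reference_sigma,
                )
            except ValueError as err:
                res = FitResult(
                    step_id=s,
                    x_bii=float("nan"),
                    fitted_weights=current[s],
                    delta_w={c: 0.0 for c in current[s].weights},
                    refit_observables=population_average(current[s], table),
                    skipped=True,
                    message=str(err),
                )
            stage_results[s] = res
        current = {s: r.fitted_weights for s, r in stage_results.items()}
        results = stage_results
        if reference_step in current:
            reference_sigma = population_average(
                current[reference_step], table
            ).sigma

    # score the final populations against experiment
    final_obs = {s: population_average(current[s], table) for s in step_ids}
    if reference_step in current:
        from .averaging import reference_delta

        referenced = reference_delta(final_obs.values(), reference_step)
        deltas = {o.step_id: o.delta for o in referenced}
    else:
        deltas = {s: float("nan") for s in step_ids}
    reports = {
        "j": mad(
            {s: final_obs[s].j_coupling for s in step_ids},
            {s: float(exp.loc[s, "j_exp"]) for s in step_ids},
            observable="j",
        ),
        "delta": mad(
            deltas,
            {s: float(exp.loc[s, "delta"]) for s in step_ids},
            observable="delta",
        ),
    }
    # recompute delta_w against the original populations
    for s, r in results.items():
        if not r.skipped:
            all_ids = set(weights[s].weights) | set(current[s].weights)
            r.delta_w = {
                c: weights[s].weights.get(c, 0.0) - current[s].weights.get(c, 0.0)
                for c in sorted(all_ids)
            }
    return results, reports
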