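"""Differential analysis of a temperature series of DNA phosphate data.

Shifts and populations measured or computed at several temperatures are
compared against a baseline (20 degC by convention): per step and
temperature the record carries the shift change d_delta = delta(T) -
delta(T0) and sectional population changes d_w for the groups
BI = {BB00, BB01}, BII = {BB04, BB07} and "rest" (everything else).
Because the three sections partition the population, the sectional d_w sum
to zero at every (step, T).  No smoothing or trend fitting is applied —
the analysis reports raw differentials only.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from .averaging import ObservableSet
from .ensembles import PopulationTable

__all__ = [
    "SECTIONS",
    "TemperatureSeries",
    "differential_series",
    "shift_range",
]

#: Default sectional grouping of NtC classes for population differentials.
SECTIONS: dict[str, frozenset[str]] = {
    "BI": frozenset({"BB00", "BB01"}),
    "BII": frozenset({"BB04", "BB07"}),
}


@dataclasses.dataclass
class TemperatureSeries:
    """Observables and populations indexed by temperature (degC).

    Each temperature maps step_id -> ObservableSet (with delta set) and
    step_id -> PopulationTable; all temperatures must cover the same steps.
    """

    observables: dict[float, dict[str, ObservableSet]]
    populations: dict[float, dict[str, PopulationTable]]

    def __post_init__(self) -> None:
        temps = set(self.observables)
        if temps != set(self.populations):
            raise ValueError("observables and populations cover different temperatures")
        step_sets = {t: frozenset(self.observables[t]) for t in temps}
        if len(set(step_sets.values())) > 1:
            raise ValueError(f"step sets differ across temperatures: {step_sets}")
        for t in temps:
            if frozenset(self.populations[t]) != step_sets[t]:
                raise ValueError(f"populations at {t} degC cover different steps")

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.observables)

    @property
    def steps(self) -> list[str]:
        first = self.observables[self.temperatures[0]]
        return list(first)


def _sectional_weights(
    pop: PopulationTable, sections: Mapping[str, frozenset[str]]
) -> dict[str, float]:
    out = {}
    assigned: set[str] = set()
    for name, members in sections.items():
        out[name] = sum(pop.weight(c) for c in members)
        assigned |= set(members)
    out["rest"] = sum(w for c, w in pop.weights.items() if c not in assigned)
    return out


def differential_series(
    series: TemperatureSeries,
    baseline: float = 20.0,
    sections: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Shift and sectional-population differentials against a baseline T.

    Returns a tidy frame with columns ``step_id, temperature, d_delta``
    plus one ``d_w_<section>`` column per section (including ``rest``).
    Baseline rows are identically zero.
    """
    if baseline not in series.observables:
        raise ValueError(
            f"baseline {baseline} degC not in series "
            f"(have {series.temperatures})"
        )
    sections = dict(sections) if sections is not None else dict(SECTIONS)
    rows = []
    base_obs = series.observables[baseline]
    base_pop = series.populations[baseline]
    for t in series.temperatures:
        for s in series.steps:
            obs = series.observables[t][s]
            if obs.delta is None or base_obs[s].delta is None:
                raise ValueError(f"step {s}: delta not set; reference shifts first")
            w_t = _sectional_weights(series.populations[t][s], sections)
            w_0 = _sectional_weights(base_pop[s], sections)
            row = {
                "step_id": s,
                "temperature": t,
                "d_delta": obs.delta - base_obs[s].delta,
            }
            for name in [*sections, "rest"]:
                row[f"d_w_{name.lower()}"] = w_t[name] - w_0[name]
            rows.append(row)
    return pd.DataFrame(rows)


def shift_range(deltas: Mapping[str, float] | Sequence[float]) -> float:
    """Total spread max(delta) - min(delta) over steps at one temperature."""
    values = list(deltas.values()) if isinstance(deltas, Mapping) else list(deltas)
    if len(values) < 2:
        raise ValueError(f"need at least 2 steps, got {len(values)}")
    return float(max(values) - min(values))
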