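import numpy as np
import pandas as pd
import pytest

from ntcnmr import (
    ClassTable,
    FitGroups,
    NtCClass,
    PopulationTable,
    TorsionVector,
    fit_equilibrium,
    fit_step_population,
    forward_observables,
    mad,
    population_average,
    synthetic_experiment,
)


def make_class(cid, family, sigma, j):
    return NtCClass(
        class_id=cid,
        defining_torsions=TorsionVector.from_iterable(
            [130, 250, 185, 260, 300, 175, 45, 130, 250]
        ),
        family=family,
        sigma=sigma,
        j_coupling=j,
    )


@pytest.fixture()
def fit_table():
    """BI' pool at J = 2 Hz, BII' pool at J = 6 Hz (per class), plus a
    bystander class."""
    return ClassTable(
        classes=[
            make_class("BB00", "BI_family", 282.0, 2.0),
            make_class("BB01", "BI_family", 281.0, 2.0),
            make_class("BB04", "BII_family", 278.0, 6.0),
            make_class("BB07", "BII_family", 276.0, 6.0),
            make_class("XX01", "other", 280.0, 4.0),
        ]
    )


class TestMad:
    def test_identical_vectors_zero(self):
        assert mad({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0}).mad == 0.0

    def test_hand_arithmetic(self):
        report = mad({"a": 1.0, "b": 3.0}, {"a": 0.0, "b": 1.0})
        assert report.mad == pytest.approx(np.sqrt(2.5))
        assert report.per_step_dev == {"a": 1.0, "b": 2.0}

    def test_permutation_invariant(self, rng):
        calc = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=8))}
        exp = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=8))}
        items = list(calc.items())
        rng.shuffle(items)
        assert mad(dict(items), exp).mad == pytest.approx(mad(calc, exp).mad)

    def test_homogeneous_in_deviations(self):
        calc = {"a": 1.0, "b": 3.0}
        exp = {"a": 0.0, "b": 1.0}
        scaled = {k: exp[k] + 2.5 * (calc[k] - exp[k]) for k in calc}
        assert mad(scaled, exp).mad == pytest.approx(2.5 * mad(calc, exp).mad)

    def test_mismatched_steps_listed(self):
        with pytest.raises(ValueError, match="only in exp.*'c'"):
            mad({"a": 1.0, "b": 1.0}, {"a": 1.0, "c": 1.0})


class TestForwardObservables:
    def pool_pop(self):
        return PopulationTable(
            step_id="s",
            weights={"BB00": 0.4, "BB01": 0.2, "BB04": 0.1, "BB07": 0.1, "XX01": 0.2},
        )

    def test_input_share_is_fixed_point(self, fit_table):
        pop = self.pool_pop()
        groups = FitGroups.from_weights(pop)
        x_in = 0.2 / 0.8  # BII' share of the pool
        obs = forward_observables(x_in, pop, groups, fit_table)
        base = population_average(pop, fit_table)
        assert obs.sigma == pytest.approx(base.sigma, rel=1e-12)
        assert obs.j_coupling == pytest.approx(base.j_coupling, rel=1e-12)

    def test_boundary_all_bi(self, fit_table):
        pop = self.pool_pop()
        groups = FitGroups.from_weights(pop)
        obs = forward_observables(0.0, pop, groups, fit_table)
        # pool mass 0.8 all at J=2, bystander 0.2 at J=4
        assert obs.j_coupling == pytest.approx(0.8 * 2.0 + 0.2 * 4.0)

    def test_affine_in_x(self, fit_table):
        pop = self.pool_pop()
        groups = FitGroups.from_weights(pop)
        vals = [forward_observables(x, pop, groups, fit_table).j_coupling
                for x in (0.0, 0.5, 1.0)]
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2, rel=1e-12)

    def test_non_pool_weights_untouched(self, fit_table):
        pop = self.pool_pop()
        groups = FitGroups.from_weights(pop)
        res = fit_step_population(3.0, pop, groups, fit_table, observable="j")
        assert res.fitted_weights.weights["XX01"] == pop.weights["XX01"]

    def test_empty_pool_is_error(self, fit_table):
        pop = PopulationTable(step_id="s", weights={"XX01": 1.0})
        groups = FitGroups()
        with pytest.raises(ValueError, match="pool"):
            forward_observables(0.5, pop, FitGroups.from_weights(pop), fit_table)


class TestFitStep:
    def simple_pop(self):
        # pool only, 50/50 BI'/BII' start
        return PopulationTable(
            step_id="s", weights={"BB00": 0.3, "BB01": 0.2, "BB04": 0.3, "BB07": 0.2}
        )

    def test_interior_solution(self, fit_table):
        pop = self.simple_pop()
        res = fit_step_population(
            3.0, pop, FitGroups.from_weights(pop), fit_table, observable="j"
        )
        # J(x) = 2(1-x) + 6x over the pure pool -> x = 0.25
        assert res.x_bii == pytest.approx(0.25, abs=1e-12)
        assert not res.clamped
        assert res.refit_observables.j_coupling == pytest.approx(3.0, abs=1e-12)

    def test_target_at_lower_boundary(self, fit_table):
        pop = self.simple_pop()
        res = fit_step_population(
            2.0, pop, FitGroups.from_weights(pop), fit_table, observable="j"
        )
        assert res.x_bii == 0.0 and not res.clamped

    def test_target_outside_range_clamped(self, fit_table):
        pop = self.simple_pop()
        res = fit_step_population(
            7.0, pop, FitGroups.from_weights(pop), fit_table, observable="j"
        )
        assert res.x_bii == 1.0 and res.clamped

    def test_degenerate_pool_is_error(self):
        table = ClassTable(
            classes=[
                make_class("BB00", "BI_family", 280.0, 3.0),
                make_class("BB07", "BII_family", 279.0, 3.0),  # same J
            ]
        )
        pop = PopulationTable(step_id="s", weights={"BB00": 0.5, "BB07": 0.5})
        with pytest.raises(ValueError, match="degenerate"):
            fit_step_population(
                3.0, pop, FitGroups.from_weights(pop), table, observable="j"
            )

    def test_delta_fit_needs_reference(self, fit_table):
        pop = self.simple_pop()
        with pytest.raises(ValueError, match="reference_sigma"):
            fit_step_population(
                0.5, pop, FitGroups.from_weights(pop), fit_table, observable="delta"
            )


class TestFitEquilibrium:
    def weights_for(self, table, x_by_step):
        """Pool-only populations with known BII' fractions per step."""
        out = {}
        for s, x in x_by_step.items():
            out[s] = PopulationTable(
                step_id=s,
                weights={
                    "BB00": 0.6 * (1 - x),
                    "BB01": 0.4 * (1 - x),
                    "BB04": 0.5 * x,
                    "BB07": 0.5 * x,
                    "XX01": 0.0,
                },
            )
        return out

    def test_self_consistent_data_leaves_populations_unchanged(self, fit_table):
        x_true = {"A6pT7": 0.1, "C1pG2": 0.5, "G2pC3": 0.3}
        weights = self.weights_for(fit_table, x_true)
        exp = synthetic_experiment(weights, fit_table, seed=0)
        results, reports = fit_equilibrium(exp, weights, fit_table)
        for s, r in results.items():
            assert not r.skipped
            for dw in r.delta_w.values():
                assert abs(dw) <= 1e-10
        assert reports["j"].mad <= 1e-10
        assert reports["delta"].mad <= 1e-10

    def test_zero_noise_recovery_of_generating_fractions(self, fit_table):
        x_true = {"A6pT7": 0.15, "C1pG2": 0.7, "G2pC3": 0.4, "C3pG4": 0.05}
        truth = self.weights_for(fit_table, x_true)
        exp = synthetic_experiment(truth, fit_table, seed=0)
        # start the fit from deliberately wrong populations
        start = self.weights_for(fit_table, {s: 0.5 for s in x_true})
        results, reports = fit_equilibrium(exp, start, fit_table)
        for s in x_true:
            assert results[s].x_bii == pytest.approx(x_true[s], abs=1e-10)
        assert reports["j"].mad <= 1e-10
        assert reports["delta"].mad <= 1e-10

    def test_noisy_recovery_within_slope_bound(self, fit_table):
        noise_j = 0.4
        x_true = {"A6pT7": 0.15, "C1pG2": 0.6}
        truth = self.weights_for(fit_table, x_true)
        start = self.weights_for(fit_table, {s: 0.5 for s in x_true})
        groups = FitGroups.from_weights(start["C1pG2"])
        v0 = forward_observables(0.0, start["C1pG2"], groups, fit_table).j_coupling
        v1 = forward_observables(1.0, start["C1pG2"], groups, fit_table).j_coupling
        slope = v1 - v0
        errors = []
        for rep in range(200):
            exp = synthetic_experiment(truth, fit_table, noise_j=noise_j, seed=1000 + rep)
            results, _ = fit_equilibrium(exp, start, fit_table, stages=("j",))
            errors.append(abs(results["C1pG2"].x_bii - x_true["C1pG2"]))
        # |x_hat - x| = |noise| / |slope|; its median is 0.6745 sd/|slope|,
        # so the sample median over 200 replicates stays below sd/|slope|
        assert np.median(errors) < noise_j / abs(slope)

    def test_missing_experimental_step_is_error(self, fit_table):
        weights = self.weights_for(fit_table, {"A6pT7": 0.2, "C1pG2": 0.5})
        exp = synthetic_experiment(weights, fit_table, seed=0)
        exp = exp[exp["step_id"] != "C1pG2"]
        with pytest.raises(ValueError, match="C1pG2"):
            fit_equilibrium(exp, weights, fit_table)

    def test_unknown_stage_rejected(self, fit_table):
        weights = self.weights_for(fit_table, {"A6pT7": 0.2})
        exp = synthetic_experiment(weights, fit_table, seed=0)
        with pytest.raises(ValueError, match="stage"):
            fit_equilibrium(exp, weights, fit_table, stages=("sigma",))
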