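import dataclasses

import numpy as np
import pandas as pd
import pytest

from ntcnmr import (
    ClassHistograms,
    ClassTable,
    JointHistogram,
    NtCClass,
    ObservableSet,
    PopulationTable,
    TorsionHistogram,
    TorsionVector,
    population_average,
    probability_average,
    reference_delta,
    rereference_experimental,
)


def scalar_class(cid, family, sigma, j, eps=185.0):
    return NtCClass(
        class_id=cid,
        defining_torsions=TorsionVector.from_iterable(
            [130, 250, eps, 260, 300, 175, 45, 130, 250]
        ),
        family=family,
        sigma=sigma,
        j_coupling=j,
    )


@pytest.fixture()
def two_class_table():
    return ClassTable(
        classes=[
            scalar_class("AA", "other", 10.0, 2.0),
            scalar_class("BB", "other", 20.0, 6.0),
        ]
    )


class TestPopulationAverage:
    def test_point_mass_returns_class_scalars(self, two_class_table):
        pop = PopulationTable(step_id="s", weights={"AA": 1.0})
        obs = population_average(pop, two_class_table)
        assert obs.sigma == 10.0 and obs.j_coupling == 2.0

    def test_even_blend(self, two_class_table):
        pop = PopulationTable(step_id="s", weights={"AA": 0.5, "BB": 0.5})
        obs = population_average(pop, two_class_table)
        assert obs.sigma == pytest.approx(15.0)
        assert obs.j_coupling == pytest.approx(4.0)

    def test_linear_in_weights(self, two_class_table):
        p1 = PopulationTable(step_id="s", weights={"AA": 0.8, "BB": 0.2})
        p2 = PopulationTable(step_id="s", weights={"AA": 0.2, "BB": 0.8})
        blend = PopulationTable(step_id="s", weights={"AA": 0.5, "BB": 0.5})
        o1 = population_average(p1, two_class_table)
        o2 = population_average(p2, two_class_table)
        ob = population_average(blend, two_class_table)
        assert ob.sigma == pytest.approx((o1.sigma + o2.sigma) / 2, rel=1e-12)
        assert ob.j_coupling == pytest.approx((o1.j_coupling + o2.j_coupling) / 2, rel=1e-12)

    def test_missing_class_parameters_named(self, two_class_table):
        pop = PopulationTable(step_id="s", weights={"CC": 1.0})
        with pytest.raises(KeyError, match="CC"):
            population_average(pop, two_class_table)


def family_table_with_constant_grids(sigma=12.0, j=3.0):
    cls = scalar_class("BB00", "BI_family", sigma, j)
    cls.sigma_surface = np.full((36, 36), sigma)
    cls.j_curve = np.full(36, j)
    other = scalar_class("XX", "other", 20.0, 5.0)
    return ClassTable(classes=[cls, other])


def uniform_histograms(cid="BB00"):
    return ClassHistograms(
        joint_alpha_zeta=JointHistogram(
            class_id=cid, grid=np.full((36, 36), 1 / 36**2), n_frames=100
        ),
        epsilon=TorsionHistogram(
            class_id=cid, torsion_name="epsilon", bins=np.full(36, 1 / 36),
            n_frames=100,
        ),
    )


class TestProbabilityAverage:
    def test_constant_grids_reduce_to_population_average(self):
        table = family_table_with_constant_grids()
        pop = PopulationTable(step_id="s", weights={"BB00": 0.7, "XX": 0.3})
        pa = population_average(pop, table)
        pr = probability_average(pop, {"BB00": uniform_histograms()}, table)
        assert pr.sigma == pytest.approx(pa.sigma, abs=1e-12)
        assert pr.j_coupling == pytest.approx(pa.j_coupling, abs=1e-12)

    def test_point_mass_histogram_picks_single_grid_value(self):
        table = family_table_with_constant_grids()
        table["BB00"].sigma_surface = np.zeros((36, 36))
        table["BB00"].sigma_surface[4, 7] = 99.0
        grid = np.zeros((36, 36))
        grid[4, 7] = 1.0
        hists = {
            "BB00": ClassHistograms(
                joint_alpha_zeta=JointHistogram(class_id="BB00", grid=grid, n_frames=5),
                epsilon=TorsionHistogram(
                    class_id="BB00", torsion_name="epsilon",
                    bins=np.eye(36)[10], n_frames=5,
                ),
            )
        }
        pop = PopulationTable(step_id="s", weights={"BB00": 1.0})
        obs = probability_average(pop, hists, table)
        assert obs.sigma == pytest.approx(99.0)

    def test_two_bin_curve_hand_value(self):
        table = family_table_with_constant_grids()
        curve = np.zeros(36)
        curve[0], curve[1] = 2.0, 6.0
        table["BB00"].j_curve = curve
        bins = np.zeros(36)
        bins[0], bins[1] = 0.25, 0.75
        hists = {
            "BB00": ClassHistograms(
                joint_alpha_zeta=JointHistogram(
                    class_id="BB00", grid=np.full((36, 36), 1 / 36**2), n_frames=4
                ),
                epsilon=TorsionHistogram(
                    class_id="BB00", torsion_name="epsilon", bins=bins, n_frames=4
                ),
            )
        }
        pop = PopulationTable(step_id="s", weights={"BB00": 1.0})
        assert probability_average(pop, hists, table).j_coupling == pytest.approx(5.0)

    def test_family_class_without_grids_rejected(self):
        table = family_table_with_constant_grids()
        table["BB00"].sigma_surface = None
        pop = PopulationTable(step_id="s", weights={"BB00": 1.0})
        with pytest.raises(ValueError, match="sigma_surface"):
            probability_average(pop, {"BB00": uniform_histograms()}, table)


def obs(step, sigma):
    return ObservableSet(step_id=step, sigma=sigma, j_coupling=0.0)


class TestReferenceDelta:
    def test_reference_step_is_exactly_zero(self):
        out = reference_delta([obs("A6pT7", 280.0), obs("C1pG2", 279.5)])
        by = {o.step_id: o.delta for o in out}
        assert by["A6pT7"] == 0.0
        assert by["C1pG2"] == pytest.approx(0.5)

    def test_equal_shielding_gives_zero_everywhere(self):
        out = reference_delta([obs("A6pT7", 280.0), obs("X", 280.0), obs("Y", 280.0)])
        assert all(o.delta == 0.0 for o in out)

    def test_constant_shielding_offset_leaves_delta_unchanged(self):
        base = [obs("A6pT7", 280.0), obs("X", 278.9), obs("Y", 281.3)]
        shifted = [dataclasses.replace(o, sigma=o.sigma + 5.0) for o in base]
        d0 = {o.step_id: o.delta for o in reference_delta(base)}
        d1 = {o.step_id: o.delta for o in reference_delta(shifted)}
        for s in d0:
            assert d1[s] == pytest.approx(d0[s], abs=1e-12)

    def test_missing_reference_is_error(self):
        with pytest.raises(ValueError, match="A6pT7"):
            reference_delta([obs("X", 280.0)])


class TestRereferenceExperimental:
    def test_hand_arithmetic(self):
        exp = pd.DataFrame(
            {"step_id": ["A6pT7", "C1pG2"], "delta_prime": [-4.21, -3.84]}
        )
        out = rereference_experimental(exp)
        by = dict(zip(out["step_id"], out["delta"]))
        assert by["C1pG2"] == pytest.approx(0.37)
        assert by["A6pT7"] == 0.0

    def test_equal_shifts_all_zero(self):
        exp = pd.DataFrame({"step_id": ["A6pT7", "X"], "delta_prime": [-4.0, -4.0]})
        assert (rereference_experimental(exp)["delta"] == 0.0).all()

    def test_idempotent(self):
        exp = pd.DataFrame(
            {"step_id": ["A6pT7", "X", "Y"], "delta_prime": [-4.21, -3.84, -4.5]}
        )
        once = rereference_experimental(exp)
        twice = rereference_experimental(
            once.assign(delta_prime=once["delta"])
        )
        np.testing.assert_allclose(twice["delta"], once["delta"], atol=1e-15)

    def test_missing_reference_is_error(self):
        exp = pd.DataFrame({"step_id": ["X"], "delta_prime": [1.0]})
        with pytest.raises(ValueError, match="A6pT7"):
            rereference_experimental(exp)
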