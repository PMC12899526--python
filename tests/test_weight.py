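import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from primetime_br.weight import (BMIDistribution, ReferenceIndividual,
                                 calibrate, equilibrium_weight_change,
                                 initialize_balance, prevalence,
                                 reduced_form_trajectory, shift_distribution,
                                 simulate, simulate_batch)


@pytest.fixture(scope="module")
def reference_adult():
    return ReferenceIndividual("male", 40.0, 1.75, 85.0)


@pytest.fixture(scope="module")
def reference_state(reference_adult):
    return initialize_balance(reference_adult)


@pytest.fixture(scope="module")
def deficit_trajectory(reference_state):
    # sustained 100 kJ/day reduction, long horizon for the asymptote
    return simulate(reference_state, -100.0, 60.0)


class TestInitialization:
    def test_equilibrium_holds_weight_for_a_decade(self, reference_state):
        tr = simulate(reference_state, 0.0, 10.0)
        assert abs(tr.weights[-1] - tr.weights[0]) < 0.1

    def test_mass_closure(self, reference_state):
        assert reference_state.body_weight == pytest.approx(85.0)
        assert reference_state.fat_mass > 0
        assert reference_state.lean_mass > 0

    def test_heavier_individual_has_more_fat(self):
        light = initialize_balance(ReferenceIndividual("male", 40, 1.75, 70.0))
        heavy = initialize_balance(ReferenceIndividual("male", 40, 1.75, 95.0))
        assert heavy.fat_mass > light.fat_mass

    def test_nonphysical_anthropometry_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndividual("male", 40, 1.0, 70.0)
        with pytest.raises(ValueError):
            ReferenceIndividual("male", 40, 1.75, -5.0)


class TestDeficitDynamics:
    def test_100kj_deficit_loses_about_one_kilogram(self, deficit_trajectory):
        dw = deficit_trajectory.weights[-1] - deficit_trajectory.weights[0]
        assert dw == pytest.approx(-1.0, abs=0.2)

    def test_half_of_change_near_one_year(self, deficit_trajectory):
        dw_inf = deficit_trajectory.weights[-1] - deficit_trajectory.weights[0]
        frac1 = (deficit_trajectory.at(1.0) - deficit_trajectory.weights[0]) / dw_inf
        assert frac1 == pytest.approx(0.50, abs=0.10)

    def test_95pct_of_change_near_three_years(self, deficit_trajectory):
        dw_inf = deficit_trajectory.weights[-1] - deficit_trajectory.weights[0]
        frac3 = (deficit_trajectory.at(3.0) - deficit_trajectory.weights[0]) / dw_inf
        assert frac3 == pytest.approx(0.95, abs=0.10)

    def test_zero_deficit_flat_trajectory(self, reference_state):
        tr = simulate(reference_state, 0.0, 5.0)
        assert np.allclose(tr.weights, tr.weights[0], atol=1e-9)

    def test_monotone_approach_to_asymptote(self, deficit_trajectory):
        assert (np.diff(deficit_trajectory.weights) <= 1e-12).all()

    def test_agrees_with_reduced_form_within_20pct_pointwise(
        self, reference_state, deficit_trajectory
    ):
        red = reduced_form_trajectory(-100.0, deficit_trajectory.times)
        dw = deficit_trajectory.delta_weights
        scale = abs(equilibrium_weight_change(-100.0))
        assert np.max(np.abs(dw - red)) <= 0.20 * scale

    def test_asymptote_matches_reduced_form_oracle_within_15pct(self, reference_state):
        for dei in (-500.0, -250.0, 250.0):
            tr = simulate(reference_state, dei, 60.0)
            dw = tr.weights[-1] - tr.weights[0]
            assert dw == pytest.approx(
                equilibrium_weight_change(dei), rel=0.15
            )

    def test_asymptotic_change_monotone_in_intake_change(self, reference_state):
        dws = []
        for dei in (-300.0, -150.0, 0.0, 150.0):
            tr = simulate(reference_state, dei, 40.0)
            dws.append(tr.weights[-1] - tr.weights[0])
        assert (np.diff(dws) > 0).all()

    def test_step_above_weekly_rejected(self, reference_state):
        with pytest.raises(ValueError):
            simulate(reference_state, -100.0, 1.0, step=1.0 / 10.0)

    def test_batch_matches_scalar_path(self, reference_state):
        times, weights = simulate_batch([reference_state] * 2, [-100.0, 0.0], 5.0)
        tr = simulate(reference_state, -100.0, 5.0)
        assert np.allclose(weights[0], tr.weights, atol=1e-10)
        assert np.allclose(weights[1], reference_state.body_weight, atol=1e-9)


class TestReducedForm:
    @pytest.mark.parametrize("dei,expected", [(-100.0, -1.0), (0.0, 0.0), (-200.0, -2.0)])
    def test_equilibrium_rule(self, dei, expected):
        assert equilibrium_weight_change(dei) == pytest.approx(expected)


class TestBMIDistribution:
    def test_shift_moves_mean_by_weight_over_height_squared(self):
        d = BMIDistribution(27.0, 4.0)
        shifted = shift_distribution(d, -1.531, 1.75)
        assert shifted.mean == pytest.approx(27.0 - 1.531 / 1.75**2)
        assert shifted.mean == pytest.approx(26.5, abs=1e-3)
        assert shifted.sd == d.sd

    def test_zero_shift_is_identity(self):
        d = BMIDistribution(27.0, 4.0)
        assert shift_distribution(d, 0.0, 1.7) == d

    def test_taller_stratum_smaller_bmi_shift(self):
        d = BMIDistribution(27.0, 4.0)
        short = shift_distribution(d, -1.0, 1.60)
        tall = shift_distribution(d, -1.0, 1.90)
        assert abs(tall.mean - 27.0) < abs(short.mean - 27.0)

    def test_prevalence_normal_cdf_oracle(self):
        d = BMIDistribution(27.0, 4.0)
        p = prevalence(d)
        assert p["obesity"] == pytest.approx(1 - stats.norm.cdf(0.75), abs=1e-10)
        assert p["obesity"] == pytest.approx(0.2266, abs=5e-4)
        shifted = shift_distribution(d, -0.5 * 1.75**2, 1.75)
        assert prevalence(shifted)["obesity"] == pytest.approx(
            1 - stats.norm.cdf(0.875), abs=1e-10
        )

    def test_tiny_sd_below_cutpoint_vanishing_prevalence(self):
        d = BMIDistribution(24.0, 1e-6)
        p = prevalence(d)
        assert p["overweight"] == pytest.approx(0.0, abs=1e-12)
        assert p["obesity"] == pytest.approx(0.0, abs=1e-12)

    @given(shift=st.floats(0.0, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_downward_shift_never_raises_obesity(self, shift):
        d = BMIDistribution(28.0, 4.5)
        moved = shift_distribution(d, -shift, 1.0)
        assert prevalence(moved)["obesity"] <= prevalence(d)["obesity"] + 1e-12


class TestCalibrate:
    def test_inverts_normal_quantile(self):
        d = calibrate(27.0, 0.2266)
        assert d.sd == pytest.approx(4.0, abs=5e-3)

    def test_round_trips_targets(self):
        for family in ("normal", "lognormal"):
            d = calibrate(28.0, 0.30, family=family)
            assert prevalence(d)["obesity"] == pytest.approx(0.30, abs=1e-6)

    def test_median_at_cutpoint_degenerate(self):
        d = calibrate(30.0, 0.5)
        assert prevalence(d)["obesity"] == pytest.approx(0.5, abs=1e-9)

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ValueError):
            calibrate(32.0, 0.2)  # mean above cut needs obesity > 0.5
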