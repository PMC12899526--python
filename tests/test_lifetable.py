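import numpy as np
import pytest

from primetime_br.disease import AGES, DiseaseEpi
from primetime_br.lifetable import (DiabetesMediation, DiscreteBMI,
                                    RelativeRisk, SimConfig,
                                    adjusted_incidence, compare,
                                    cost_stream, diabetes_adjust, discount,
                                    pif, qaly_stream, run_cohort)
from primetime_br.synthetic import make_toy_lifetable
from primetime_br.weight import BMIDistribution

from oracles import pif_mass_points, present_value, toy_lifetable

N = len(AGES)
RR = RelativeRisk("t2dm", "male", 2.0, reference_bmi=22.5)


class TestPIF:
    def test_identical_distributions_give_zero(self):
        d = BMIDistribution(27.0, 4.0)
        assert pif(d, d, RR) == pytest.approx(0.0, abs=1e-12)

    def test_unit_relative_risk_gives_zero(self):
        rr1 = RelativeRisk("t2dm", "male", 1.0)
        d0 = BMIDistribution(28.0, 4.0)
        d1 = BMIDistribution(26.0, 4.0)
        assert pif(d0, d1, rr1) == pytest.approx(0.0, abs=1e-12)

    def test_mass_point_enumeration_exact(self):
        # F0 = {0.5 @ RR=2, 0.5 @ RR=1}, F1 = {0.4 @ RR=2, 0.6 @ RR=1}
        # PIF = (1.5 - 1.4) / 1.5
        d0 = DiscreteBMI((27.5, 22.5), (0.5, 0.5))
        d1 = DiscreteBMI((27.5, 22.5), (0.4, 0.6))
        val = pif(d0, d1, RR)
        assert val == pytest.approx((1.5 - 1.4) / 1.5, abs=1e-12)
        assert val == pytest.approx(0.0667, abs=1e-4)

    def test_matches_enumeration_oracle_to_1e10(self):
        pts0, w0 = (24.0, 29.0, 34.5), (0.3, 0.5, 0.2)
        pts1, w1 = (23.5, 28.2, 33.0), (0.35, 0.5, 0.15)
        got = pif(DiscreteBMI(pts0, w0), DiscreteBMI(pts1, w1), RR)
        want = pif_mass_points(pts0, w0, pts1, w1, 2.0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_continuous_downward_shift_positive_pif(self):
        d0 = BMIDistribution(28.0, 4.2)
        d1 = BMIDistribution(27.7, 4.2)
        assert 0.0 < pif(d0, d1, RR) < 1.0


class TestIncidenceAdjustment:
    def test_pif_scaling(self):
        i = np.full(N, 0.02)
        assert adjusted_incidence(i, np.zeros(N)) == pytest.approx(i)
        assert adjusted_incidence(i, np.full(N, 0.1))[0] == pytest.approx(0.018)
        assert (adjusted_incidence(i, np.ones(N)) == 0).all()

    def test_pif_above_one_rejected(self):
        with pytest.raises(ValueError):
            adjusted_incidence(np.full(N, 0.02), np.full(N, 1.1))

    def test_diabetes_adjust_hand_value(self):
        i = np.array([0.01])
        out = diabetes_adjust(i, np.array([0.10]), np.array([0.08]), 2.0)
        assert out[0] == pytest.approx(0.01 * 1.08 / 1.10)

    @pytest.mark.parametrize("p0,p1,rr", [(0.1, 0.1, 2.0), (0.1, 0.05, 1.0)])
    def test_diabetes_adjust_neutral_cases(self, p0, p1, rr):
        i = np.array([0.01])
        out = diabetes_adjust(i, np.array([p0]), np.array([p1]), rr)
        assert out[0] == pytest.approx(0.01)


class TestDiscount:
    def test_zero_rate_plain_sum(self):
        assert discount(np.array([1.0, 2.0, 3.0]), 0.0) == pytest.approx(6.0)

    def test_two_year_unit_stream_at_5pct(self):
        assert discount(np.array([1.0, 1.0]), 0.05) == pytest.approx(
            1.0 + 1.0 / 1.05, abs=1e-12
        )
        assert discount(np.array([1.0, 1.0]), 0.05) == pytest.approx(1.9524, abs=1e-4)

    def test_monotone_in_rate(self):
        stream = np.linspace(3.0, 1.0, 30)
        pvs = [discount(stream, r) for r in (0.0, 0.03, 0.05, 0.10)]
        assert all(a > b for a, b in zip(pvs, pvs[1:]))

    def test_matches_loop_oracle(self):
        stream = [5.0, 4.0, 3.0, 2.0]
        assert discount(np.array(stream), 0.07) == pytest.approx(
            present_value(stream, 0.07), abs=1e-12
        )


def toy_run(pif_value=0.0):
    toy = make_toy_lifetable()
    pifs = None
    if pif_value:
        surf = np.full((N, toy["config"].n_cycles), pif_value)
        pifs = {"ihd": surf}
    return run_cohort(
        epi=toy["epi"], pifs=pifs, config=toy["config"],
        population=toy["population"], all_cause_mortality=toy["all_cause"],
        sex="male",
    )


class TestCohortRun:
    def test_background_only_matches_standard_life_table(self):
        epi = {"ihd": DiseaseEpi("ihd", "male", np.zeros(N), np.zeros(N), np.zeros(N))}
        pop = np.zeros(N); pop[0] = 1000.0
        bg = np.linspace(0.01, 0.5, N)
        cfg = SimConfig(n_cycles=30, diabetes_mediation=False)
        run = run_cohort(epi, None, cfg, pop, bg, "male")
        expected = 1000.0 * np.exp(-np.cumsum(bg[:30]))
        assert np.allclose(run.alive[0, 1:31], expected, rtol=1e-9)

    def test_conservation_every_cycle(self, pipeline):
        for sex in ("male", "female"):
            assert pipeline.baseline_run(sex).conservation_error() < 1e-9

    def test_toy_cohort_matches_spreadsheet_oracle(self):
        run = toy_run()
        oracle = toy_lifetable(
            pops=[1000.0, 1000.0, 1000.0], i=0.10, f=0.05, bg=0.02,
            p0=0.10, decrement=0.2, n_cycles=3,
        )
        for t in range(3):
            assert np.allclose(
                run.alive[:3, t + 1], oracle["survivors"][t], atol=1e-9
            )
            assert run.cases["ihd"][:3, t].sum() == pytest.approx(
                oracle["cases"][t], abs=1e-9
            )
        got_qaly = qaly_stream(run, {"ihd": 0.2})
        assert np.allclose(got_qaly, oracle["qaly"], atol=1e-9)

    def test_toy_survivors_frozen_values(self):
        # values computed once with the scalar spreadsheet oracle
        # (oracles.toy_lifetable) and frozen here
        run = toy_run()
        assert run.alive[0, 2] == pytest.approx(939.7862660507, abs=1e-6)
        assert run.cases["ihd"][:3, 0].sum() == pytest.approx(256.9389713029, abs=1e-6)
        assert qaly_stream(run, {"ihd": 0.2})[0] == pytest.approx(
            2846.9327908050, abs=1e-6
        )

    def test_missing_decrement_rejected(self):
        run = toy_run()
        with pytest.raises(KeyError):
            qaly_stream(run, {})


class TestOutcomes:
    def test_identical_runs_give_zero_delta(self):
        r0 = toy_run()
        r1 = toy_run()
        cfg = make_toy_lifetable()["config"]
        costs = {"ihd": np.full(N, 100.0)}
        delta = compare(r0, r1, cfg, {"ihd": 0.2}, costs)
        assert delta.qaly_gained == 0.0
        assert delta.cost_saving_int == 0.0
        assert all(v == 0.0 for v in delta.cases_averted.values())

    def test_pif_produces_cases_averted_equal_to_incidence_difference(self):
        r0 = toy_run()
        r1 = toy_run(pif_value=0.3)
        cfg = make_toy_lifetable()["config"]
        delta = compare(r0, r1, cfg, {"ihd": 0.2}, {"ihd": np.zeros(N)})
        oracle0 = toy_lifetable([1000.0] * 3, 0.10, 0.05, 0.02, 0.10, 0.2, 3)
        oracle1 = toy_lifetable([1000.0] * 3, 0.10, 0.05, 0.02, 0.10, 0.2, 3, pif=0.3)
        want = sum(oracle0["cases"]) - sum(oracle1["cases"])
        assert delta.cases_averted["ihd"] == pytest.approx(want, rel=1e-9)
        assert delta.cases_averted["ihd"] > 0

    def test_hhd_zero_cost_contract(self, bundle):
        costs = bundle.cost_per_case("male")
        assert not costs["hhd"].any()

    def test_incident_cost_arithmetic(self):
        # 100 incident cases at a 500/case one-off cost -> 50,000 that year
        run = toy_run()
        run.cases["ihd"][:, :] = 0.0
        run.cases["ihd"][0, 0] = 100.0
        run.prevalence["ihd"][:, :] = 0.0
        stream = cost_stream(run, {"ihd": np.full(N, 500.0)})
        assert stream[0] == pytest.approx(50_000.0)
        assert stream[1:] == pytest.approx(0.0)

    def test_mismatched_cohorts_rejected(self):
        r0 = toy_run()
        r1 = toy_run()
        r1.population = r1.population.copy()
        r1.population[0] += 1.0
        cfg = make_toy_lifetable()["config"]
        with pytest.raises(ValueError):
            compare(r0, r1, cfg, {"ihd": 0.2}, {"ihd": np.zeros(N)})


class TestMediation:
    def test_lower_diabetes_prevalence_lowers_ihd_incidence(self):
        i = np.full(3, 0.02)
        out = diabetes_adjust(i, np.full(3, 0.2), np.full(3, 0.15), 2.0)
        assert (out < i).all()

    def test_invalid_rr_rejected(self):
        with pytest.raises(ValueError):
            DiabetesMediation(-1.0, 1.8)
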