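import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import registrysim as rs
from registrysim.netsurv import (LifetableCoverageError, _excess_hazard_curve,
                                 _step_lookup)

from _oracles import oracle_survival_at, pohar_perme_oracle


class TestLifetable:
    def test_rejects_gaps_and_negative_rates(self):
        with pytest.raises(ValueError):
            rs.Lifetable(np.array([0.0, 2.0]), np.array([1.0, 3.0]),
                         np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            rs.Lifetable(np.array([0.0]), np.array([1.0]), np.array([-0.1]))

    def test_cumulative_piecewise_values(self):
        lt = rs.Lifetable(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]),
                          np.array([0.1, 0.2, 0.4]))
        assert lt.cumulative_at(0.0) == 0.0
        assert lt.cumulative_at(1.5) == pytest.approx(0.1 + 0.2 * 0.5)
        assert lt.cumulative_at(3.0) == pytest.approx(0.7)
        assert lt.expected_cumhaz(0.5, 2.0) == pytest.approx(
            0.05 + 0.2 + 0.4 * 0.5)

    def test_unit_and_generic_band_paths_agree(self):
        rates = np.array([0.1, 0.1, 0.3, 0.3])
        unit = rs.Lifetable(np.arange(4.0), np.arange(1.0, 5.0), rates)
        merged = rs.Lifetable(np.array([0.0, 2.0]), np.array([2.0, 4.0]),
                              np.array([0.1, 0.3]))
        a = np.linspace(0.0, 4.0, 33)
        assert np.allclose(unit.cumulative_at(a), merged.cumulative_at(a),
                           atol=1e-14)

    def test_coverage_error_beyond_support(self):
        lt = rs.Lifetable(np.array([0.0]), np.array([10.0]), np.array([0.1]))
        with pytest.raises(LifetableCoverageError):
            lt.cumulative_at(11.0)


class TestKaplanMeierReduction:
    def test_equals_km_exactly_with_zero_expected_rates(self, cohort_a):
        """Zero lifetable: weights are 1 and the estimator is the all-cause KM."""
        from lifelines import KaplanMeierFitter

        frame = cohort_a.estimation_frame().iloc[:500]
        lt0 = rs.Lifetable.zero(0.0, 120.0)
        est = rs.pohar_perme(frame, lt0, (1.0, 5.0),
                             age_groups=((0.0, 120.0),), weights=[1.0])
        km = KaplanMeierFitter().fit(frame["time"], frame["dead"])
        for j, t in enumerate((1.0, 5.0)):
            assert est.survival[j] == pytest.approx(
                float(km.survival_function_at_times(t).iloc[0]), abs=1e-12)

    def test_standardised_km_reduction_per_group(self, cohort_a):
        from lifelines import KaplanMeierFitter

        frame = cohort_a.estimation_frame().iloc[:1000]
        lt0 = rs.Lifetable.zero(0.0, 120.0)
        est = rs.pohar_perme(frame, lt0, (5.0,))
        w = est.weights
        combined = 0.0
        for g, (lo, hi) in enumerate(est.age_groups):
            sub = frame[(frame["age"] >= lo) & (frame["age"] < hi)]
            km = KaplanMeierFitter().fit(sub["time"], sub["dead"])
            combined += w[g] * float(km.survival_function_at_times(5.0).iloc[0])
        assert est.survival[0] == pytest.approx(combined, abs=1e-12)


class TestBruteForceOracle:
    def test_three_subject_toy(self, toy_frame, flat_lifetable):
        """Deaths at 1 and 2, censor at 2.5, flat 0.1/yr expected rate."""
        est = rs.pohar_perme(toy_frame, flat_lifetable, (2.0,),
                             age_groups=((0.0, 120.0),), weights=[1.0])
        expected = oracle_survival_at(
            toy_frame["time"].tolist(), toy_frame["dead"].tolist(),
            toy_frame["age"].tolist(), [0.0], [120.0], [0.1], 2.0)
        assert est.survival[0] == pytest.approx(expected, abs=1e-10)

    @given(
        n=st.integers(1, 6),
        data=st.data(),
    )
    @settings(max_examples=80)
    def test_all_small_cohorts_match_oracle(self, n, data):
        """Property: implementation equals the term-by-term oracle to 1e-10
        on arbitrary small cohorts and piecewise-constant lifetables."""
        # times on a coarse grid so ties are exact, never approximate
        times = data.draw(st.lists(
            st.integers(1, 80).map(lambda k: k * 0.1), min_size=n, max_size=n))
        dead = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        ages = data.draw(st.lists(
            st.integers(20, 90).map(float), min_size=n, max_size=n))
        n_bands = data.draw(st.integers(1, 4))
        edges = np.linspace(0.0, 120.0, n_bands + 1)
        rates = data.draw(st.lists(
            st.floats(0.0, 0.5), min_size=n_bands, max_size=n_bands))
        lt = rs.Lifetable(edges[:-1], edges[1:], np.array(rates))
        frame = pd.DataFrame({"age": ages, "time": times, "dead": dead})
        tp = 5.0
        est = rs.pohar_perme(frame, lt, (tp,), age_groups=((0.0, 120.0),),
                             weights=[1.0])
        expected = oracle_survival_at(times, dead, ages, list(edges[:-1]),
                                      list(edges[1:]), rates, tp)
        # compare before clamping when the oracle strays outside [0, 1]
        grid, surv, _ = _excess_hazard_curve(
            np.array(times), np.array(dead), np.array(ages), lt, tp)
        raw = float(_step_lookup(grid, surv, np.array([tp]))[0])
        assert raw == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_cause_specific_km_on_simulated_data(self):
        """With other-cause mortality fully captured by the lifetable, the
        estimator tracks the cause-specific KM computed from known causes."""
        from lifelines import KaplanMeierFitter

        scen = rs.scenario("A", n_cases=8000)
        cancer = rs.calibrate_baseline(scen)
        other = scen.other_spec()
        lt = rs.make_lifetable(other, p_x=scen.p_x)
        coh = rs.simulate_cohort(scen, cancer, other, seed=42)
        est = rs.pohar_perme(coh.estimation_frame(), lt, (5.0,),
                             age_groups=((18.0, 111.0),), weights=[1.0])
        km = KaplanMeierFitter().fit(coh.data["t_observed"],
                                     coh.data["cause"] == "cancer")
        cs = float(km.survival_function_at_times(5.0).iloc[0])
        assert est.survival[0] == pytest.approx(cs, abs=0.02)


class TestEstimatorStructure:
    def test_step_convention_right_continuous(self, flat_lifetable):
        df = pd.DataFrame({"age": [50.0, 50.0], "time": [1.0, 3.0],
                           "dead": [True, True]})
        est = rs.pohar_perme(df, flat_lifetable, (0.5, 1.0, 2.0),
                             age_groups=((0.0, 120.0),), weights=[1.0])
        assert est.survival[0] == 1.0          # before the first death
        assert est.survival[1] < 1.0           # jump exactly at t = 1
        assert est.survival[2] == est.survival[1]  # constant between deaths

    def test_survival_clamped_at_reporting(self):
        """Huge expected rates push net survival above 1; reported values
        are clamped while the raw curve is not."""
        lt = rs.Lifetable(np.array([0.0]), np.array([120.0]), np.array([2.0]))
        df = pd.DataFrame({"age": [50.0] * 6, "time": [4.0] * 5 + [4.5],
                           "dead": [False] * 5 + [True]})
        grid, surv, _ = _excess_hazard_curve(
            df["time"].to_numpy(), df["dead"].to_numpy(),
            df["age"].to_numpy(), lt, 5.0)
        assert surv.max() > 1.0
        est = rs.pohar_perme(df, lt, (5.0,), age_groups=((0.0, 120.0),),
                             weights=[1.0])
        assert est.survival[0] == 1.0

    def test_by_x_strata_are_plain_subset_estimates(self, cohort_a, lifetable_a):
        frame = cohort_a.estimation_frame()
        full = rs.pohar_perme(frame[frame["x"] == 1], lifetable_a, (5.0,))
        again = rs.pohar_perme(frame[frame["x"] == 1], lifetable_a, (5.0,),
                               stratum="x=1")
        assert np.array_equal(full.survival, again.survival)

    def test_non_identifiable_flagged(self, flat_lifetable):
        df = pd.DataFrame({"age": [50.0, 55.0], "time": [1.0, 2.0],
                           "dead": [True, False]})
        est = rs.pohar_perme(df, flat_lifetable, (1.0, 5.0),
                             age_groups=((0.0, 120.0),), weights=[1.0])
        assert est.identifiable[0]
        assert not est.identifiable[1]

    def test_empty_input_raises(self, flat_lifetable):
        with pytest.raises(ValueError):
            rs.pohar_perme(pd.DataFrame(columns=["age", "time", "dead"]),
                           flat_lifetable)

    def test_empty_age_group_merged(self, flat_lifetable):
        """A band with no subjects hands its weight to the nearest neighbour."""
        df = pd.DataFrame({"age": [40.0, 42.0, 60.0, 61.0],
                           "time": [1.0, 2.0, 1.5, 3.0],
                           "dead": [True, True, True, False]})
        est = rs.pohar_perme(df, flat_lifetable, (3.0,),
                             age_groups=((18.0, 55.0), (55.0, 65.0),
                                         (65.0, 75.0), (75.0, 111.0)),
                             weights=[0.25, 0.25, 0.25, 0.25])
        assert np.isfinite(est.survival[0])
        assert est.weights.sum() == pytest.approx(1.0)
        assert est.weights[2] == 0.0 and est.weights[3] == 0.0


class TestAgeStandardise:
    def test_convexity_fixed_point(self):
        assert rs.age_standardise([0.4, 0.4, 0.4], [0.2, 0.3, 0.5]) == \
            pytest.approx(0.4)

    def test_degenerate_weights_select_group(self):
        assert rs.age_standardise([0.9, 0.1, 0.5, 0.2], [1.0, 0.0, 0.0, 0.0]) \
            == pytest.approx(0.9)

    def test_hand_computed_weighted_sum(self):
        got = rs.age_standardise([0.8, 0.6], [0.3, 0.7])
        assert got == pytest.approx(0.3 * 0.8 + 0.7 * 0.6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            rs.age_standardise([0.5, 0.5], [0.5, 0.6])
        with pytest.raises(ValueError):
            rs.age_standardise([np.nan, 0.5], [0.5, 0.5])

    def test_internal_weights_sum_to_one(self):
        w = rs.internal_age_weights()
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).all()
        # 75+ is the heaviest band under Normal(70, 15) truncated to [18, 100]
        assert w[3] == w.max()


class TestEderer2:
    def test_matches_pohar_perme_under_zero_rates(self, cohort_a):
        frame = cohort_a.estimation_frame().iloc[:300]
        lt0 = rs.Lifetable.zero(0.0, 120.0)
        pp = rs.pohar_perme(frame, lt0, (5.0,), age_groups=((0.0, 120.0),),
                            weights=[1.0])
        e2 = rs.ederer2(frame, lt0, (5.0,), age_groups=((0.0, 120.0),),
                        weights=[1.0])
        assert e2.survival[0] == pytest.approx(pp.survival[0], abs=1e-12)

    def test_close_to_pohar_perme_on_real_lifetable(self, cohort_a, lifetable_a):
        frame = cohort_a.estimation_frame().iloc[:2000]
        pp = rs.pohar_perme(frame, lifetable_a, (5.0,))
        e2 = rs.ederer2(frame, lifetable_a, (5.0,))
        assert abs(pp.survival[0] - e2.survival[0]) < 0.05
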