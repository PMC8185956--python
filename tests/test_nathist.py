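"""Unit and property tests for the natural-history simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baycann.nathist import (AGE_GROUP_STARTS, STATES, CohortTrace,
                             LifeTable, ModelOutputs, NaturalHistoryParams,
                             build_generator, run_cohort, run_microsim,
                             summarize_outputs, transition_matrix,
                             weibull_adenoma_hazard)

S = {name: i for i, name in enumerate(STATES)}


def _quiescent_params(**kw):
    """Parameters with all progression switched off unless overridden."""
    base = dict(l=0.0, gamma=1.0, lambda2=0.0, lambda3=0.0, lambda4=0.0,
                lambda5=0.0, lambda6=0.0, lambda7=0.0, lambda8=0.0,
                p_adeno=0.0, p_small=0.0, p_preclin_early=0.0,
                p_preclin_late=0.0)
    base.update(kw)
    return NaturalHistoryParams(**base)


def _flat_life_table(mu=0.0):
    ages = np.arange(50, 101)
    return LifeTable(ages, np.full(len(ages), mu))


class TestWeibullHazard:
    @pytest.mark.parametrize("l,gamma,a,expected", [
        (2.86e-6, 2.78, 1.0, 2.86e-6 * 2.78),  # a^(gamma-1) = 1
        (0.05, 1.0, 37.0, 0.05),  # shape 1 reduces to a constant hazard
    ])
    def test_closed_form_values(self, l, gamma, a, expected):
        assert weibull_adenoma_hazard(l, gamma, a) == pytest.approx(
            expected, rel=1e-12)

    def test_age_power_against_log_exp_oracle(self):
        # independent evaluation of l*gamma*50^1.78 via log/exp
        expected = 2.86e-6 * 2.78 * math.exp(1.78 * math.log(50.0))
        assert weibull_adenoma_hazard(2.86e-6, 2.78, 50.0) == pytest.approx(
            expected, rel=1e-12)

    @given(gamma=st.floats(1.0 + 1e-6, 6.0),
           l=st.floats(1e-8, 1e-3),
           a1=st.floats(1.0, 80.0), a2=st.floats(1.0, 80.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_age_for_shape_above_one(self, gamma, l, a1, a2):
        lo, hi = sorted([a1, a2])
        h_lo = weibull_adenoma_hazard(l, gamma, lo)
        h_hi = weibull_adenoma_hazard(l, gamma, hi)
        assert h_hi >= h_lo

    def test_rejects_nonpositive_age(self):
        with pytest.raises(ValueError):
            weibull_adenoma_hazard(1e-6, 2.0, 0.0)
        with pytest.raises(ValueError):
            weibull_adenoma_hazard(1e-6, 0.0, 50.0)


class TestGenerator:
    def test_all_rates_zero_gives_zero_matrix(self):
        Q = build_generator(_quiescent_params(), 50.0, 0.0)
        assert np.all(Q == 0.0)

    def test_rows_sum_to_zero(self, base_params):
        Q = build_generator(base_params, 63.0, 0.004)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_adenoma_onset_entry_matches_hazard(self, base_params):
        Q = build_generator(base_params, 50.0, 0.003)
        expected = weibull_adenoma_hazard(2.86e-6, 2.78, 50.0)
        assert Q[S["normal"], S["small_adenoma"]] == pytest.approx(expected)

    def test_death_rows_absorbing(self, base_params):
        Q = build_generator(base_params, 70.0, 0.01)
        assert np.all(Q[S["crc_death"]] == 0.0)
        assert np.all(Q[S["other_death"]] == 0.0)

    def test_arrow_structure(self, base_params):
        Q = build_generator(base_params, 55.0, 0.002)
        p = base_params
        assert Q[S["small_adenoma"], S["large_adenoma"]] == p.lambda2
        assert Q[S["large_adenoma"], S["preclin_early"]] == p.lambda3
        assert Q[S["preclin_early"], S["preclin_late"]] == p.lambda4
        assert Q[S["preclin_early"], S["clin_early"]] == p.lambda5
        assert Q[S["preclin_late"], S["clin_late"]] == p.lambda6
        assert Q[S["clin_early"], S["crc_death"]] == p.lambda7
        assert Q[S["clin_late"], S["crc_death"]] == p.lambda8
        # every alive state flows to background death
        for s in range(7):
            assert Q[s, S["other_death"]] == 0.002


def _series_expm(Q, terms=30):
    """Independent scaled-and-squared truncated Taylor series oracle."""
    norm = np.abs(Q).sum(axis=1).max()
    s = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 1)
    A = Q / 2 ** s
    P = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms + 1):
        term = term @ A / k
        P = P + term
    for _ in range(s):
        P = P @ P
    return P


class TestTransitionMatrix:
    def test_zero_generator_gives_identity(self):
        assert np.allclose(transition_matrix(np.zeros((9, 9))), np.eye(9))

    def test_two_state_closed_form(self):
        r = 0.31
        Q = np.array([[-r, r], [0.0, 0.0]])
        P = transition_matrix(Q, dt=1.0)
        assert P[0, 1] == pytest.approx(1.0 - math.exp(-r), abs=1e-12)

    def test_agrees_with_series_oracle_on_random_generators(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = 9
            Q = rng.uniform(0.0, 0.8, (n, n))
            Q[rng.random((n, n)) < 0.5] = 0.0
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            assert np.abs(transition_matrix(Q) - _series_expm(Q)).max() < 1e-10

    def test_rows_are_probability_distributions(self, base_params):
        Q = build_generator(base_params, 80.0, 0.02)
        P = transition_matrix(Q)
        assert np.all(P >= 0.0) and np.all(P <= 1.0)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10

    def test_rejects_non_generator(self):
        bad = np.eye(9)  # positive diagonal
        with pytest.raises(ValueError):
            transition_matrix(bad)


class TestCohort:
    def test_nothing_moves_when_all_rates_zero(self):
        trace = run_cohort(_quiescent_params(), _flat_life_table(0.0))
        expected = np.zeros(9)
        expected[0] = 1.0
        assert np.allclose(trace.occupancy, expected)

    def test_rows_sum_to_one(self, base_params, life_table):
        trace = run_cohort(base_params, life_table)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-10

    def test_absorbing_states_monotone(self, base_params, life_table):
        trace = run_cohort(base_params, life_table)
        for state in ("crc_death", "other_death"):
            occ = trace.occupancy[:, S[state]]
            assert np.all(np.diff(occ) >= -1e-12)
        assert trace.occupancy[-1, S["other_death"]] > trace.occupancy[1, S["other_death"]]

    def test_initial_distribution_row(self, base_params, life_table):
        trace = run_cohort(base_params, life_table)
        assert np.allclose(trace.occupancy[0],
                           base_params.initial_distribution())

    def test_life_table_gap_rejected(self, base_params):
        short = LifeTable(np.arange(50, 70), np.full(20, 0.01))
        with pytest.raises(ValueError):
            run_cohort(base_params, short)

    def test_trace_roundtrip_csv(self, base_params, life_table, tmp_path):
        trace = run_cohort(base_params, life_table)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header[0] == "age"
        assert header[1:10] == list(STATES)
        assert header[-2:] == ["inflow_clin_early", "inflow_clin_late"]


class TestSummaries:
    def test_cohort_all_normal_has_zero_prevalence(self):
        trace = run_cohort(_quiescent_params(), _flat_life_table())
        out = summarize_outputs(trace)
        assert np.all(out.adenoma_prev == 0.0)

    def test_constant_equal_adenoma_occupancy_gives_half_small(self):
        n_ages = 46
        occ = np.zeros((n_ages, 9))
        occ[:, S["small_adenoma"]] = 0.2
        occ[:, S["large_adenoma"]] = 0.2
        occ[:, S["normal"]] = 0.6
        trace = CohortTrace(np.arange(50, 96), occ,
                            np.zeros(n_ages - 1), np.zeros(n_ages - 1))
        out = summarize_outputs(trace)
        assert np.allclose(out.prop_small, 0.5)
        assert np.allclose(out.adenoma_prev, 0.4)

    def test_output_vector_has_36_entries(self, base_params, life_table):
        out = summarize_outputs(run_cohort(base_params, life_table))
        assert out.to_vector().shape == (36,)
        assert len(ModelOutputs.column_names()) == 36

    def test_outputs_lie_in_unit_interval(self, base_params, life_table):
        v = summarize_outputs(run_cohort(base_params, life_table)).to_vector()
        assert np.all(v >= 0.0) and np.all(v <= 1.0)

    def test_vector_roundtrip_and_ordering(self):
        v = np.arange(36) / 36.0
        out = ModelOutputs.from_vector(v)
        assert np.allclose(out.to_vector(), v)
        # canonical ordering: series alphabetical, then ascending age group
        names = ModelOutputs.column_names()
        assert names[0] == "adenoma_prev_50"
        assert names == sorted(names, key=lambda s: (s.rsplit("_", 1)[0],
                                                     int(s.rsplit("_", 1)[1])))


class TestMicrosim:
    def test_same_seed_is_bit_identical(self, base_params):
        a = run_microsim(base_params, 2000, seed=123)
        b = run_microsim(base_params, 2000, seed=123)
        assert np.array_equal(a.to_vector(), b.to_vector())

    def test_all_small_adenomas_stay_small_without_growth(self):
        params = _quiescent_params(p_adeno=1.0, p_small=1.0)
        out = run_microsim(params, 500, _flat_life_table(0.0), seed=7)
        assert np.all(out.prop_small == 1.0)
        assert np.all(out.adenoma_prev == 1.0)

    def test_converges_to_cohort_at_large_n(self, base_params, life_table):
        """Replicate microsimulations bracket the cohort value.

        Monte-Carlo standard errors are estimated empirically from 8
        independent replicates of n=12,500 (equivalent information to one
        run of n=100,000); at that precision at least 34 of the 36 outcomes
        should fall within 3 standard errors of the deterministic value.
        """
        cohort = summarize_outputs(run_cohort(base_params, life_table)).to_vector()
        reps = np.array([
            run_microsim(base_params, 12500, life_table, seed=1000 + r).to_vector()
            for r in range(8)])
        pooled_mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        n_within = int(np.sum(np.abs(pooled_mean - cohort) <= 3.0 * se))
        assert n_within >= 34
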