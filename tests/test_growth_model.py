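"""Unit and property tests for the two-state colony growth process."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from becgrowth import (
    ColonyState,
    ModelParameters,
    ParameterDomainError,
    SizeDistribution,
    TruncationOverflowError,
    expected_counts,
    fate_probabilities,
    master_equation_distribution,
    simulate_cohort,
    simulate_colony,
    step_colony,
)
from becgrowth.growth_model import (
    empirical_size_pmf,
    simulate_states,
    total_variation,
)


class TestFateProbabilities:
    @pytest.mark.parametrize(
        "r, s, expected",
        [
            (0.15, 0.06, (0.21, 0.70, 0.09)),  # fitted values
            (0.15, 0.0, (0.15, 0.70, 0.15)),  # balanced limit is symmetric
            (0.5, 0.0, (0.5, 0.0, 0.5)),
            (0.0, 0.0, (0.0, 1.0, 0.0)),
        ],
    )
    def test_mapping(self, r, s, expected):
        f = fate_probabilities(r, s)
        assert (f.prob_pp, f.prob_pq, f.prob_qq) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "r, s, fragment",
        [
            (0.10, 0.2, "r - s"),  # prob_QQ negative
            (0.6, 0.0, "1 - 2r"),  # prob_PQ negative
            (0.5, 0.6, "r - s"),
        ],
    )
    def test_domain_errors_name_the_inequality(self, r, s, fragment):
        with pytest.raises(ParameterDomainError, match=fragment):
            fate_probabilities(r, s)

    @settings(derandomize=True, max_examples=200)
    @given(
        r=st.floats(0.0, 0.5, allow_nan=False),
        s=st.floats(0.0, 0.5, allow_nan=False),
    )
    def test_valid_region_yields_a_distribution(self, r, s):
        if s > r or r + s > 1:
            return
        f = fate_probabilities(r, s)
        probs = [f.prob_pp, f.prob_pq, f.prob_qq]
        assert all(-1e-12 <= q <= 1 + 1e-12 for q in probs)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)


class TestModelParameters:
    def test_defaults_are_the_fitted_set(self, fitted_params):
        assert fitted_params.as_dict() == {
            "p": 0.465, "m": 0.175, "r": 0.15, "s": 0.06, "l": 0.001, "lag_days": 6,
        }

    @pytest.mark.parametrize("bad", [{"p": 1.2}, {"m": -0.1}, {"l": 2}, {"lag_days": -1}])
    def test_rejects_out_of_domain(self, bad):
        with pytest.raises(ParameterDomainError):
            ModelParameters(**bad)

    def test_week_to_growth_days_conversion(self, fitted_params):
        # 8 weeks minus the 6-day proliferation lag -> 50 growth days
        assert fitted_params.growth_days(8) == 50
        assert fitted_params.growth_days(0) == 0
        assert ModelParameters(lag_days=0).growth_days(2) == 14


class TestStepColony:
    def test_no_division_no_loss_is_identity(self, rng):
        params = ModelParameters(m=0.0, l=0.0)
        state = ColonyState(n_p=3, n_q=2, day=5)
        out = step_colony(state, params, rng)
        assert (out.n_p, out.n_q, out.day) == (3, 2, 6)

    def test_certain_loss_empties_the_colony(self, rng):
        params = ModelParameters(m=0.5, l=1.0)
        out = step_colony(ColonyState(n_p=4, n_q=4), params, rng)
        assert (out.n_p, out.n_q) == (0, 0)

    def test_one_step_kernel_frequencies(self):
        """Empirical one-day outcome frequencies from a single P cell match
        the enumerated kernel within 3 binomial standard errors."""
        params = ModelParameters(m=0.175, r=0.15, s=0.06, l=0.0)
        n = 100_000
        rng = np.random.default_rng(11)
        n_p, n_q = simulate_states(np.ones(n, dtype=bool), params, 1, rng)
        expected = {
            (1, 0): 1 - 0.175,
            (2, 0): 0.175 * 0.21,
            (1, 1): 0.175 * 0.70,
            (0, 2): 0.175 * 0.09,
        }
        for (i, j), prob in expected.items():
            freq = np.mean((n_p == i) & (n_q == j))
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(freq - prob) < 3 * se, (i, j)


class TestSimulateColony:
    def test_quiescent_founder_never_grows(self, fitted_params, rng):
        params = ModelParameters(l=0.0)
        traj = simulate_colony(False, params, 30, rng)
        assert all(st.size == 1 and st.n_p == 0 for st in traj.states)

    def test_zero_days_is_the_founder_alone(self, fitted_params, rng):
        traj = simulate_colony(True, fitted_params, 0, rng)
        assert len(traj) == 1
        assert traj.final == ColonyState(n_p=1, n_q=0, day=0)

    def test_irreversibility_and_growth_bounds(self):
        """n_P at most doubles per day; with l=0 the quiescent pool and the
        colony size never shrink, and a colony whose P pool empties stays put."""
        params = ModelParameters(p=1.0, l=0.0)
        for seed in range(20):
            traj = simulate_colony(True, params, 40, np.random.default_rng(seed))
            for a, b in zip(traj.states, traj.states[1:]):
                assert b.n_p <= 2 * a.n_p
                assert b.n_q >= a.n_q
                assert b.size >= a.size
                if a.n_p == 0:
                    assert b.n_p == 0 and b.size == a.size

    def test_bit_reproducible(self, fitted_params):
        t1 = simulate_colony(True, fitted_params, 25, np.random.default_rng(5))
        t2 = simulate_colony(True, fitted_params, 25, np.random.default_rng(5))
        assert t1 == t2

    def test_trajectory_dataframe_columns(self, fitted_params, rng):
        df = simulate_colony(True, fitted_params, 3, rng).to_dataframe("c1")
        assert list(df.columns) == ["colony_id", "day", "n_P", "n_Q"]
        assert df["day"].tolist() == [0, 1, 2, 3]


class TestExpectedCounts:
    def test_balanced_lossless_process_is_critical(self):
        params = ModelParameters(s=0.0, l=0.0)
        for t in (0, 1, 10, 100):
            e_p, _ = expected_counts(params, t)
            assert e_p == pytest.approx(1.0)

    def test_day_zero(self, fitted_params):
        assert expected_counts(fitted_params, 0) == (1.0, 0.0)

    def test_one_step_value(self):
        e_p, e_q = expected_counts(ModelParameters(l=0.0), 1)
        assert e_p == pytest.approx(1.021)
        # one division (prob m) contributes prob_PQ + 2 prob_QQ quiescent cells
        assert e_q == pytest.approx(0.175 * (0.70 + 2 * 0.09))

    def test_matches_master_equation_means(self, fitted_params):
        dist = master_equation_distribution(fitted_params, 8, max_cells=64)
        assert dist.expected_counts() == pytest.approx(
            expected_counts(fitted_params, 8), abs=1e-8
        )

    @pytest.mark.parametrize(
        "params",
        [
            ModelParameters(),
            ModelParameters(m=0.3, r=0.2, s=0.0, l=0.0),
            ModelParameters(m=0.1, r=0.05, s=0.02, l=0.01),
            ModelParameters(m=0.5, r=0.4, s=0.1, l=0.005),
            ModelParameters(m=0.2, r=0.25, s=0.1, l=0.0),
        ],
    )
    def test_cohort_mean_matches_closed_form(self, params):
        n, days = 30_000, 15
        rng = np.random.default_rng(77)
        n_p, _ = simulate_states(np.ones(n, dtype=bool), params, days, rng)
        e_p, _ = expected_counts(params, days)
        se = n_p.std(ddof=1) / np.sqrt(n)
        assert abs(n_p.mean() - e_p) < 3 * se


class TestSimulateCohort:
    def test_all_quiescent_founders_have_unit_size(self, rng):
        dist = simulate_cohort(500, ModelParameters(p=0.0, l=0.0), 20, rng)
        assert dist.support.tolist() == [1.0]
        assert dist.total == 500

    def test_point_mass_without_division(self, rng):
        dist = simulate_cohort(200, ModelParameters(p=1.0, m=0.0, l=0.0), 10, rng)
        assert dist.support.tolist() == [1.0]

    def test_extinct_colonies_reported_not_listed(self, rng):
        dist = simulate_cohort(2000, ModelParameters(p=1.0, m=0.0, l=0.05), 20, rng)
        assert dist.n_extinct > 0
        assert dist.total + dist.n_extinct == 2000
        assert np.all(dist.support >= 1)

    def test_mean_size_monotone_in_days_m_and_s(self):
        """Mean final size is non-decreasing in the horizon, the division
        probability and the imbalance, under common random numbers."""
        def mean_size(m=0.175, s=0.06, days=20):
            params = ModelParameters(p=1.0, m=m, s=s, l=0.0)
            rng = np.random.default_rng(99)
            n_p, n_q = simulate_states(np.ones(4000, dtype=bool), params, days, rng)
            return (n_p + n_q).mean()

        assert mean_size(days=10) <= mean_size(days=20) <= mean_size(days=35)
        assert mean_size(m=0.1) <= mean_size(m=0.2) <= mean_size(m=0.35)
        assert mean_size(s=0.0) <= mean_size(s=0.05) <= mean_size(s=0.1)

    def test_cohort_bit_reproducible(self, fitted_params):
        d1 = simulate_cohort(300, fitted_params, 15, np.random.default_rng(3))
        d2 = simulate_cohort(300, fitted_params, 15, np.random.default_rng(3))
        assert np.array_equal(d1.support, d2.support)
        assert np.array_equal(d1.counts, d2.counts)


class TestMasterEquation:
    def test_day_zero_is_a_point_mass(self, fitted_params):
        dist = master_equation_distribution(fitted_params, 0, max_cells=8)
        assert dist.pmf[1, 0] == 1.0
        assert dist.truncated_mass == 0.0

    def test_day_one_matches_hand_enumeration(self):
        params = ModelParameters(m=0.175, r=0.15, s=0.06, l=0.0)
        dist = master_equation_distribution(params, 1, max_cells=8)
        assert dist.pmf[1, 0] == pytest.approx(0.825)
        assert dist.pmf[2, 0] == pytest.approx(0.175 * 0.21)
        assert dist.pmf[1, 1] == pytest.approx(0.175 * 0.70)
        assert dist.pmf[0, 2] == pytest.approx(0.175 * 0.09)

    def test_probability_is_conserved(self, fitted_params):
        dist = master_equation_distribution(fitted_params, 12, max_cells=64)
        assert dist.pmf.sum() + dist.truncated_mass == pytest.approx(1.0, abs=1e-9)
        assert dist.truncated_mass < 1e-6

    def test_quiescent_founder_only_decays(self):
        params = ModelParameters(l=0.01)
        dist = master_equation_distribution(
            params, 5, max_cells=8, founder_proliferative=False
        )
        assert dist.pmf[0, 1] == pytest.approx(0.99**5)
        assert dist.pmf[0, 0] == pytest.approx(1 - 0.99**5)

    def test_truncation_overflow_raises(self):
        params = ModelParameters(p=1.0, m=0.9, r=0.5, s=0.5, l=0.0)  # pure PP growth
        with pytest.raises(TruncationOverflowError) as err:
            master_equation_distribution(params, 10, max_cells=4)
        assert err.value.truncated_mass > 1e-6

    def test_monte_carlo_agrees_at_small_horizon(self, fitted_params):
        dist = master_equation_distribution(fitted_params, 6, max_cells=32)
        rng = np.random.default_rng(17)
        n_p, n_q = simulate_states(np.ones(100_000, dtype=bool), fitted_params, 6, rng)
        pmf = dist.size_pmf()
        emp = empirical_size_pmf(n_p + n_q, len(pmf))
        assert total_variation(pmf, emp) < 0.01


class TestSizeDistribution:
    def test_binning_conserves_counts(self):
        dist = SizeDistribution.from_sizes([1, 1, 2, 4, 7, 30])
        binned = dist.binned()
        assert binned.total == 6
        assert binned.counts.tolist() == [2, 1, 1, 1, 0, 1]

    def test_csv_round_trip(self, tmp_path):
        dist = SizeDistribution.from_sizes([1, 2, 2, 5, 9])
        path = tmp_path / "dist.csv"
        dist.to_csv(path)
        back = SizeDistribution.from_csv(path)
        assert np.array_equal(back.support, dist.support)
        assert np.array_equal(back.counts, dist.counts)

    def test_binned_csv_round_trip(self, tmp_path):
        binned = SizeDistribution.from_sizes([1, 2, 3, 10, 50]).binned()
        path = tmp_path / "binned.csv"
        binned.to_csv(path)
        back = SizeDistribution.from_csv(path)
        assert np.array_equal(back.bin_edges, binned.bin_edges)
        assert np.array_equal(back.counts, binned.counts)

    def test_uncovered_sizes_rejected(self):
        dist = SizeDistribution.from_sizes([1, 2, 3])
        with pytest.raises(ValueError, match="cover"):
            dist.binned([2, 3, 4])
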