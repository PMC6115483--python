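import numpy as np
import pytest

from shiftsim import (
    InfeasibleLoadError,
    InvalidParameterError,
    MotorUnitPool,
    RecruitmentPolicy,
    draw_shift,
    expected_recruitment_ratio,
    generate_pool,
    selection_weights,
)


def exact_expected_R(forces, weights, load):
    """Exhaustive-enumeration oracle for E[R].

    Sums over every sequential sampling path (recruit one unit at a
    time with renormalized weights, stop once accumulated force meets
    the load), weighting each recruited-count by the path probability.
    Tractable for n <= ~6.
    """
    n = len(forces)
    if load <= 0:
        return 0.0

    def rec(remaining, acc, prob):
        if acc >= load:
            return prob * (n - len(remaining)) / n
        if not remaining:
            return prob * 1.0
        wsum = sum(weights[j] for j in remaining)
        return sum(
            rec(remaining - {j}, acc + forces[j], prob * weights[j] / wsum)
            for j in remaining
        )

    return rec(frozenset(range(n)), 0.0, 1.0)


class TestSelectionWeights:
    def test_uniform_weights(self, uniform):
        pool = MotorUnitPool(np.array([1.0, 5.0, 9.0, 20.0]))
        np.testing.assert_allclose(selection_weights(pool, uniform), np.full(4, 0.25))

    def test_zero_bias_equals_uniform(self, pool100):
        np.testing.assert_array_equal(
            selection_weights(pool100, RecruitmentPolicy.small_biased(0.0)),
            selection_weights(pool100, RecruitmentPolicy.uniform()),
        )

    def test_inverse_force_weighting(self):
        # forces (1, 2) at bias 1: raw weights 1 and 1/2 -> (2/3, 1/3)
        pool = MotorUnitPool(np.array([1.0, 2.0]))
        np.testing.assert_allclose(
            selection_weights(pool, RecruitmentPolicy.small_biased(1.0)),
            [2.0 / 3.0, 1.0 / 3.0],
        )

    def test_weights_positive_sum_to_one(self, pool100, biased):
        w = selection_weights(pool100, biased)
        assert np.all(w > 0)
        assert w.sum() == pytest.approx(1.0)
        # strictly decreasing with force
        assert np.all(np.diff(w) < 0)

    @pytest.mark.parametrize("kwargs", [{"kind": "onion_skin"}, {"bias_strength": -1.0}])
    def test_invalid_policy_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            RecruitmentPolicy(**{"kind": "small_biased", **kwargs})


class TestDrawShift:
    def test_equal_force_pool_needs_ceiling_count(self, equal4, uniform):
        # load of 2.5 unit-forces always needs exactly 3 equal units
        for seed in range(50):
            rec = draw_shift(equal4, 2.5, uniform, rng=seed)
            assert len(rec.recruited) == 3
            assert rec.recruitment_ratio == 0.75
            assert rec.total_force == 3.0

    def test_zero_load_empty_shift(self, pool100, uniform):
        rec = draw_shift(pool100, 0.0, uniform, rng=0)
        assert rec.recruited == frozenset()
        assert rec.recruitment_ratio == 0.0
        assert rec.total_force == 0.0

    def test_full_load_recruits_everyone(self, pool100, biased):
        rec = draw_shift(pool100, pool100.max_strength, biased, rng=0)
        assert rec.recruitment_ratio == 1.0
        assert len(rec.recruited) == pool100.n

    def test_infeasible_load_raises(self, pool100, uniform):
        with pytest.raises(InfeasibleLoadError):
            draw_shift(pool100, 1.001 * pool100.max_strength, uniform, rng=0)

    def test_negative_load_raises(self, pool100, uniform):
        with pytest.raises(InvalidParameterError):
            draw_shift(pool100, -1.0, uniform, rng=0)

    @pytest.mark.parametrize("policy_kind", ["uniform", "small_biased"])
    @pytest.mark.parametrize("fraction", [0.1, 0.37, 0.5, 0.85])
    def test_force_balance_and_minimality(self, pool100, policy_kind, fraction):
        # Eq.-1 stopping: accumulated force meets the load, and dropping
        # the last-sampled unit would violate it
        policy = RecruitmentPolicy(policy_kind)
        load = fraction * pool100.max_strength
        for seed in range(10):
            rec = draw_shift(pool100, load, policy, rng=seed)
            assert rec.total_force >= load
            last = rec.order[-1]
            assert rec.total_force - pool100.forces[last] < load
            assert rec.recruitment_ratio == len(rec.recruited) / pool100.n

    def test_zero_bias_draws_identical_to_uniform(self, pool100):
        for seed in range(5):
            a = draw_shift(pool100, 800.0, RecruitmentPolicy.uniform(), rng=seed)
            b = draw_shift(pool100, 800.0, RecruitmentPolicy.small_biased(0.0), rng=seed)
            assert a.order == b.order


class TestExpectedRecruitmentRatio:
    def test_full_load_deterministic(self, pool100, uniform):
        assert expected_recruitment_ratio(pool100, pool100.max_strength, uniform, 50, rng=0) == (1.0, 0.0)

    def test_equal_force_pool_deterministic(self, equal4, uniform):
        mean, sd = expected_recruitment_ratio(equal4, 2.5, uniform, 100, rng=0)
        assert mean == 0.75
        assert sd == 0.0

    def test_half_load_gives_near_half_recruitment(self, pool100, uniform):
        # uniform sampling: recruited count fraction tracks recruited
        # force fraction, up to the last-unit overshoot (~+0.005)
        mean, _ = expected_recruitment_ratio(
            pool100, 0.5 * pool100.max_strength, uniform, 4000, rng=0
        )
        assert abs(mean - 0.5) < 0.02

    def test_expected_ratio_monotone_in_load(self, pool100, uniform):
        # common random numbers: same seed at every load
        means = [
            expected_recruitment_ratio(pool100, f * pool100.max_strength, uniform, 500, rng=3)[0]
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert np.all(np.diff(means) >= 0)

    def test_invalid_draw_count(self, pool100, uniform):
        with pytest.raises(InvalidParameterError):
            expected_recruitment_ratio(pool100, 1.0, uniform, 0, rng=0)


class TestEnumerationOracle:
    """Monte-Carlo E[R] must match exhaustive path enumeration (n <= 6)."""

    cases = [
        (np.array([1.0, 2.0, 3.0, 4.0]), 4.5, RecruitmentPolicy.uniform()),
        (np.array([1.0, 2.0, 3.0, 4.0]), 4.5, RecruitmentPolicy.small_biased(1.0)),
        (np.array([1.0, 1.5, 2.0, 5.0, 7.0]), 6.0, RecruitmentPolicy.uniform()),
        (np.array([1.0, 1.5, 2.0, 5.0, 7.0]), 6.0, RecruitmentPolicy.small_biased(1.5)),
        (np.array([2.0, 2.0, 2.0]), 3.5, RecruitmentPolicy.uniform()),
        (np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0]), 20.0, RecruitmentPolicy.small_biased(0.7)),
    ]

    @pytest.mark.parametrize("forces,load,policy", cases)
    def test_monte_carlo_matches_enumeration(self, forces, load, policy):
        pool = MotorUnitPool(forces)
        weights = selection_weights(pool, policy)
        exact = exact_expected_R(list(pool.forces), list(weights), load)
        n_draws = 40000
        mean, sd = expected_recruitment_ratio(pool, load, policy, n_draws, rng=12345)
        se = sd / np.sqrt(n_draws)
        assert abs(mean - exact) <= max(3 * se, 1e-9)

    def test_oracle_sanity_equal_forces(self):
        # 3 equal units, load 3.5 -> always 2 units: E[R] = 2/3 exactly
        assert exact_expected_R([2.0, 2.0, 2.0], [1 / 3] * 3, 3.5) == pytest.approx(2 / 3)

    def test_oracle_sanity_path_probabilities(self):
        # two units, load forces both be recruited regardless of order
        assert exact_expected_R([1.0, 3.0], [0.5, 0.5], 4.0) == pytest.approx(1.0)
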