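import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sleepcost as sc
from sleepcost.decision import (
    ASLEEP,
    AWAKE,
    ChoiceContext,
    action_utility,
    choose,
    circadian_penalty,
    waking_utility,
)


@pytest.fixture(scope="module")
def unit_params(elephant_captive):
    return elephant_captive.replace(eta=1.0, gamma=1.0, xi=1.0, mu_W=1.0)


class TestWakingUtility:
    def test_exhausted_sleep_stock_earns_nothing(self, unit_params):
        for z in (-1.0, 0.0, 2.0):
            assert waking_utility(1.0, z, unit_params) == 0.0

    def test_all_unit_case(self, unit_params):
        assert waking_utility(0.0, 0.0, unit_params) == pytest.approx(1.0)

    def test_hand_evaluated_curvature(self, elephant_captive):
        p = elephant_captive  # gamma = 0.8, eta = 1, xi = 1, mu_W = 1
        assert waking_utility(0.5, 0.0, p) == pytest.approx(0.5**0.8)
        assert 0.5**0.8 == pytest.approx(0.574349, abs=1e-6)

    def test_monotone_in_stock_and_environment(self, elephant_captive):
        u = [waking_utility(h, 0.0, elephant_captive) for h in (0.0, 0.4, 0.9)]
        assert u[0] > u[1] > u[2]
        v = [waking_utility(0.5, z, elephant_captive) for z in (-1.0, 0.0, 1.0)]
        assert v[0] < v[1] < v[2]

    def test_above_asymptote_rejected(self, elephant_captive):
        with pytest.raises(ValueError):
            waking_utility(1.5, 0.0, elephant_captive)


class TestCircadianPenalty:
    def test_on_cycle_is_free(self, elephant_captive):
        assert circadian_penalty(0.3, 0.3, elephant_captive) == 0.0

    def test_hand_evaluated(self, elephant_captive):
        assert circadian_penalty(0.0, 0.5, elephant_captive) == pytest.approx(2.5)

    def test_symmetry(self, elephant_captive):
        assert circadian_penalty(0.2, 0.9, elephant_captive) == pytest.approx(
            circadian_penalty(0.9, 0.2, elephant_captive)
        )


class TestActionUtility:
    def test_no_switch_no_lambda(self, elephant_captive):
        ctx = ChoiceContext(H_prev=0.5, A_prev=AWAKE, y=0.0, z=0.0)
        lam_free = elephant_captive.replace(lam=0.0)
        assert action_utility(ctx, AWAKE, elephant_captive) == pytest.approx(
            action_utility(ctx, AWAKE, lam_free)
        )

    def test_full_hand_computation(self, elephant_captive):
        # independent evaluation of every term for the captive elephant at
        # H_prev=0.5, previously awake, midnight (y=-1), neutral environment
        p = elephant_captive
        ctx = ChoiceContext(H_prev=0.5, A_prev=AWAKE, y=-1.0, z=0.0)
        delta = math.exp(-1.0 / (8.0 * 144 / 24))
        h_wake = 1.0 + (0.5 - 1.0) * delta
        h_sleep = -0.9056 + (0.5 + 0.9056) * delta
        expected_wake = (0.5) ** 0.8 - 10.0 * abs(h_wake + 1.0) ** 2
        expected_sleep = -10.0 * abs(h_sleep + 1.0) ** 2 - 0.2
        assert action_utility(ctx, AWAKE, p) == pytest.approx(expected_wake, rel=1e-12)
        assert action_utility(ctx, ASLEEP, p) == pytest.approx(expected_sleep, rel=1e-12)
        # at these values the sleep branch dominates
        assert choose(ctx, p).A == ASLEEP

    def test_invalid_action_rejected(self, elephant_captive):
        ctx = ChoiceContext(H_prev=0.5, A_prev=AWAKE, y=0.0, z=0.0)
        with pytest.raises(ValueError):
            action_utility(ctx, 2, elephant_captive)


class TestChoose:
    def test_equals_brute_force_on_random_contexts(self, elephant_wild, rng):
        p = elephant_wild
        n = 5000
        H = rng.uniform(p.mu_S, p.mu_W, n)
        Ap = rng.integers(0, 2, n)
        y = rng.uniform(-1, 1, n)
        z = rng.normal(0, 0.7, n)
        for i in range(n):
            ctx = ChoiceContext(H_prev=H[i], A_prev=int(Ap[i]), y=y[i], z=z[i])
            res = choose(ctx, p)
            utilities = {a: action_utility(ctx, a, p) for a in (AWAKE, ASLEEP)}
            assert res.U == max(utilities.values())
            assert utilities[res.A] == res.U

    def test_dominant_foraging_keeps_animal_awake(self, elephant_wild):
        p = elephant_wild.replace(xi=1e6)
        ctx = ChoiceContext(H_prev=0.5, A_prev=ASLEEP, y=-1.0, z=0.0)
        assert choose(ctx, p).A == AWAKE

    def test_free_sleep_toward_cycle_chosen(self, elephant_wild):
        p = elephant_wild.replace(xi=0.0, lam=0.0)
        ctx = ChoiceContext(H_prev=0.9, A_prev=AWAKE, y=-1.0, z=0.0)
        # sleeping moves H toward mu_S (and y); waking holds it near mu_W
        assert choose(ctx, p).A == ASLEEP

    def test_exact_tie_keeps_previous_action(self, elephant_captive):
        # symmetric asymptotes, equal decay, no foraging or switching cost:
        # from the midpoint both actions move H symmetrically about y=0,
        # giving identical penalties and an exact tie
        p = elephant_captive.replace(xi=0.0, lam=0.0, mu_W=1.0, mu_S=-1.0)
        for prev in (AWAKE, ASLEEP):
            ctx = ChoiceContext(H_prev=0.0, A_prev=prev, y=0.0, z=0.0)
            res = choose(ctx, p)
            assert res.U_wake == pytest.approx(res.U_sleep)
            assert res.A == prev

    @given(st.floats(min_value=0.0, max_value=20.0), st.floats(min_value=0.0, max_value=20.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_opportunity_cost(self, xi_lo, xi_hi):
        p0 = sc.preset("elephant_wild")
        lo, hi = sorted((xi_lo, xi_hi))
        ctx = ChoiceContext(H_prev=0.4, A_prev=AWAKE, y=-0.5, z=0.2)
        a_lo = choose(ctx, p0.replace(xi=lo)).A
        a_hi = choose(ctx, p0.replace(xi=hi)).A
        # raising xi can only flip sleep -> wake, never wake -> sleep
        assert not (a_lo == AWAKE and a_hi == ASLEEP)

    def test_large_kappa_recovers_two_process_band(self, elephant_wild):
        p = elephant_wild.replace(kappa=40.0, xi=0.0, lam=0.01)
        day = sc.simulate_stylized(p)
        assert np.max(np.abs(day.H - day.y)) <= 1.0 + 0.05
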