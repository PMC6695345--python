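import math

import numpy as np
import pytest

from habitrl import agents, models, stats, task, twosystem
from habitrl.models import RLParams, get_spec
from habitrl.twosystem import (TwoSystemParams, TwoSystemState,
                               apply_block_instruction,
                               devaluation_phase_go_prob,
                               learning_phase_choice_prob, learning_phase_step,
                               replay_learning)


class TestLearningPhase:
    def test_first_rewarded_trial_updates_both_systems(self):
        state = TwoSystemState()
        p = TwoSystemParams(alpha=0.5, w_goal=1.0, w_habit=1.0, tau=0.0)
        learning_phase_step(state, p, stimulus=2, chosen_response=1, reward=1)
        assert state.Q[2, 1] == pytest.approx(0.5)
        assert state.H[2, 1] == pytest.approx(0.5)

    def test_habit_grows_without_reward(self):
        state = TwoSystemState()
        p = TwoSystemParams(alpha=0.5, w_goal=1.0, w_habit=1.0, tau=0.0)
        learning_phase_step(state, p, 0, 0, reward=1)
        q_before, h_before = state.Q[0, 0], state.H[0, 0]
        learning_phase_step(state, p, 0, 0, reward=0)
        assert state.Q[0, 0] < q_before       # extinction of the goal value
        assert state.H[0, 0] > h_before       # S-R strength still grows

    def test_zero_learning_rate_freezes_values(self):
        state = TwoSystemState()
        p = TwoSystemParams(alpha=0.0, w_goal=1.0, w_habit=1.0, tau=0.5)
        learning_phase_step(state, p, 0, 1, reward=1)
        assert state.Q.sum() == 0 and state.H.sum() == 0
        assert state.C[1] == 1.0

    def test_indifference_limit(self, contingency):
        state = TwoSystemState()
        p = TwoSystemParams(alpha=0.3, w_goal=0.0, w_habit=0.0, tau=0.0)
        probs = learning_phase_choice_prob(state, p, 0, contingency)
        assert probs == pytest.approx([0.5, 0.5])

    def test_habit_biases_choice_iff_weight_positive(self, contingency):
        for w_goal in (0.0, 1.0, 4.0):
            for w_habit in (0.0, 0.5, 2.0):
                state = TwoSystemState()
                state.Q[0] = [0.5, 0.5]
                state.H[0] = [0.1, 0.8]
                p = TwoSystemParams(0.3, w_goal, w_habit, 0.0)
                probs = learning_phase_choice_prob(state, p, 0, contingency)
                if w_habit > 0:
                    assert probs[1] > 0.5
                else:
                    assert probs[1] == pytest.approx(0.5)


class TestNesting:
    def test_two_system_reduces_to_single_system(self, contingency):
        """With w_habit = 0 and all outcomes valued, the two-system learning
        likelihood equals the winning single-system model with beta = w_goal,
        to machine precision."""
        spec = get_spec("delta_softmax_persev")
        sched = task.build_learning_schedule(contingency, seed=11)
        p1 = RLParams(alpha=0.4, beta=3.5, tau=0.3)
        df = agents.simulate_learning_phase(p1, spec, sched, contingency, seed=12)
        ll_single = models.subject_log_likelihood(spec, p1, df.to_dict("records"))

        ts = TwoSystemParams(alpha=0.4, w_goal=3.5, w_habit=0.0, tau=0.3)
        state = TwoSystemState()
        ll_two = 0.0
        for rec in df.to_dict("records"):
            s, a = rec["stimulus_id"], rec["response"]
            probs = learning_phase_choice_prob(state, ts, s, contingency)
            ll_two += math.log(probs[a])
            learning_phase_step(state, ts, s, a, contingency.reward(s, a))
        assert ll_two == pytest.approx(ll_single, abs=1e-12)


class TestDevaluationPhase:
    def test_devalued_goal_drive_is_zero(self, contingency):
        state = TwoSystemState()
        s = 0
        a = contingency.correct_response[s]
        state.Q[s, a] = 1.0
        apply_block_instruction(state, frozenset([contingency.outcome_id[s]]))
        p = TwoSystemParams(alpha=0.3, w_goal=50.0, w_habit=0.0, tau=0.0)
        assert devaluation_phase_go_prob(state, p, s, contingency,
                                         "nhlat") == pytest.approx(0.5)

    def test_pure_habit_ignores_devaluation(self, contingency):
        state = TwoSystemState()
        s = 0
        a = contingency.correct_response[s]
        state.H[s, a] = 1.0
        p = TwoSystemParams(alpha=0.3, w_goal=0.0, w_habit=20.0, tau=0.0)
        apply_block_instruction(state, frozenset([contingency.outcome_id[s]]))
        p_dev = devaluation_phase_go_prob(state, p, s, contingency, "nhlat")
        apply_block_instruction(state, frozenset())
        p_val = devaluation_phase_go_prob(state, p, s, contingency, "nhlat")
        assert p_dev == pytest.approx(p_val)
        assert p_dev > 0.99

    def test_unknown_variant_rejected(self, contingency):
        state = TwoSystemState()
        p = TwoSystemParams(0.3, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            devaluation_phase_go_prob(state, p, 0, contingency, "vlat")

    def test_hlat_go_responses_strengthen_habit(self, contingency):
        state = TwoSystemState()
        s = 0
        p = TwoSystemParams(alpha=0.3, w_goal=0.0, w_habit=2.0, tau=0.1)
        probs = []
        for _ in range(10):
            pg = devaluation_phase_go_prob(state, p, s, contingency, "hlat",
                                           update=True, went=True)
            probs.append(pg)
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_nhlat_freezes_habit(self, contingency):
        state = TwoSystemState()
        s = 0
        p = TwoSystemParams(alpha=0.3, w_goal=0.0, w_habit=2.0, tau=0.0)
        h0 = state.H.copy()
        for _ in range(5):
            devaluation_phase_go_prob(state, p, s, contingency, "nhlat",
                                      update=True, went=True)
        assert (state.H == h0).all()


def _simulate_bias(ts_params, contingency, seed=0, n_agents=30):
    """Mean habit bias of simulated agents (own learning-phase replay)."""
    spec = get_spec("delta_softmax_persev")
    biases = []
    rng = np.random.default_rng(seed)
    for i in range(n_agents):
        sched = task.build_learning_schedule(contingency, seed=int(rng.integers(2**31)))
        learn = agents.simulate_learning_phase(
            RLParams(alpha=0.4, beta=4.0, tau=0.2), spec, sched, contingency,
            seed=int(rng.integers(2**31)))
        end = replay_learning(ts_params, learn.to_dict("records"), contingency)
        dsched = task.build_devaluation_schedule(contingency,
                                                 seed=int(rng.integers(2**31)))
        dev = agents.simulate_devaluation_phase(ts_params, end, dsched,
                                                contingency, "nhlat",
                                                seed=int(rng.integers(2**31)))
        dev = dev.assign(subject_id=i, group="x")
        biases.append(stats.habit_bias(dev).habit_bias)
    return float(np.mean(biases))


class TestHabitBiasBehaviour:
    def test_pure_goal_agent_strongly_negative_bias(self, contingency):
        bias = _simulate_bias(TwoSystemParams(0.4, 8.0, 0.0, 0.0), contingency)
        assert bias < -0.4

    def test_pure_habit_agent_bias_near_zero(self, contingency):
        bias = _simulate_bias(TwoSystemParams(0.4, 0.0, 6.0, 0.0), contingency)
        assert abs(bias) < 0.05

    def test_bias_monotone_in_goal_weight(self, contingency):
        biases = [_simulate_bias(TwoSystemParams(0.4, w, 1.0, 0.0), contingency,
                                 seed=3)
                  for w in (0.0, 2.0, 6.0)]
        assert biases[0] > biases[1] > biases[2]

    def test_bias_rises_toward_zero_with_habit_weight(self, contingency):
        biases = [_simulate_bias(TwoSystemParams(0.4, 4.0, w, 0.0), contingency,
                                 seed=4)
                  for w in (0.0, 1.0, 4.0)]
        assert biases[0] < biases[1] < biases[2] <= 0.05


class TestStateInvariants:
    def test_q_and_h_remain_in_unit_interval(self, contingency):
        rng = np.random.default_rng(0)
        state = TwoSystemState()
        p = TwoSystemParams(alpha=0.9, w_goal=1.0, w_habit=1.0, tau=0.0)
        for _ in range(400):
            learning_phase_step(state, p, int(rng.integers(6)),
                                int(rng.integers(2)), int(rng.integers(2)))
        for _ in range(200):
            devaluation_phase_go_prob(state, p, int(rng.integers(6)),
                                      contingency, "hlat", update=True,
                                      went=bool(rng.integers(2)))
        assert (state.Q >= 0).all() and (state.Q <= 1).all()
        assert (state.H >= 0).all() and (state.H <= 1).all()
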