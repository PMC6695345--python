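"""Two-system (goal-directed / habitual) instrumental model over both phases.

The goal-directed system learns expected outcome values Q(s, a) by a delta
rule toward the obtained reward; the habit system learns stimulus–response
strengths H(s, a) by a delta rule toward 1 on every emission of response a to
stimulus s, irrespective of reward.  Choice is a softmax over the combined
drive

    D(a) = w_goal * Q(s, a) * u(o(s, a)) + w_habit * H(s, a) + tau * C(a)

where u is the current outcome utility (1 valued, 0 devalued by instantaneous
instruction at block onset).  In the devaluation test phase the subject
chooses go vs no-go for the stimulus's learned correct response a*; P(go) is
a logistic of D(a*) against a zero no-go baseline.  Two variants cover
whether habit learning continues at test: HLAT (a go response keeps updating
H toward 1) or NHLAT (H frozen during the test phase).

A single learning rate alpha serves both systems; the task cannot dissociate
system-specific rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import N_RESPONSES, N_STIMULI
from .task import Contingency, DevaluationSchedule

VARIANTS = ("hlat", "nhlat")

#: canonical parameter order of the two-system model
TS_PARAM_NAMES = ("alpha", "w_goal", "w_habit", "tau")


@dataclass
class TwoSystemParams:
    """alpha in [0,1]; expression weights w_goal, w_habit >= 0; tau unbounded."""

    alpha: float
    w_goal: float
    w_habit: float
    tau: float

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.w_goal < 0 or self.w_habit < 0:
            raise ValueError("expression weights must be >= 0")
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")


@dataclass
class TwoSystemState:
    Q: np.ndarray = field(default_factory=lambda: np.zeros((N_STIMULI, N_RESPONSES)))
    H: np.ndarray = field(default_factory=lambda: np.zeros((N_STIMULI, N_RESPONSES)))
    u: np.ndarray = field(default_factory=lambda: np.ones(N_STIMULI))  # by outcome id
    C: np.ndarray = field(default_factory=lambda: np.zeros(N_RESPONSES))

    def copy(self) -> "TwoSystemState":
        return TwoSystemState(self.Q.copy(), self.H.copy(), self.u.copy(), self.C.copy())


def learning_phase_step(state: TwoSystemState, params: TwoSystemParams,
                        stimulus: int, chosen_response: int, reward: int) -> TwoSystemState:
    """Update Q toward the reward and H toward 1 for the emitted response."""
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    s, a = stimulus, chosen_response
    state.Q[s, a] += params.alpha * (reward - state.Q[s, a])
    state.H[s, a] += params.alpha * (1.0 - state.H[s, a])
    state.C[:] = 0.0
    state.C[a] = 1.0
    return state


def _drives(state: TwoSystemState, params: TwoSystemParams,
            stimulus: int, contingency: Contingency) -> np.ndarray:
    # the outcome delivered for (s, a) is contingency's outcome when a is
    # correct; an incorrect response earns nothing, so its goal term uses the
    # learned Q (≈0) gated by the same stimulus outcome utility
    o = contingency.outcome_id[stimulus]
    return (params.w_goal * state.Q[stimulus] * state.u[o]
            + params.w_habit * state.H[stimulus]
            + params.tau * state.C)


def learning_phase_choice_prob(state: TwoSystemState, params: TwoSystemParams,
                               stimulus: int, contingency: Contingency) -> np.ndarray:
    """Softmax over the two responses' combined drives."""
    d = _drives(state, params, stimulus, contingency)
    d = d - d.max()
    ex = np.exp(d)
    return ex / ex.sum()


def devaluation_phase_go_prob(state: TwoSystemState, params: TwoSystemParams,
                              stimulus: int, contingency: Contingency,
                              variant: str, update: bool = False,
                              went: bool | None = None) -> float:
    """P(go) for the stimulus's learned correct response against a zero no-go drive.

    With ``update=True`` the call also applies the test-phase transition for
    the (given) emitted response: under ``hlat`` a go response updates
    H(s, a*) toward 1; under ``nhlat`` H is frozen.  The perseveration
    indicator treats go as response index 0 and no-go as index 1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    s = stimulus
    a_star = contingency.correct_response[s]
    o = contingency.outcome_id[s]
    drive = (params.w_goal * state.Q[s, a_star] * state.u[o]
             + params.w_habit * state.H[s, a_star]
             + params.tau * (state.C[0] - state.C[1]))
    p_go = 1.0 / (1.0 + np.exp(-drive))
    if update:
        if went is None:
            raise ValueError("update=True requires the emitted response")
        if went and variant == "hlat":
            state.H[s, a_star] += params.alpha * (1.0 - state.H[s, a_star])
        state.C[:] = 0.0
        state.C[0 if went else 1] = 1.0
    return float(p_go)


def apply_block_instruction(state: TwoSystemState, devalued_outcomes: frozenset[int]) -> None:
    """Instantaneous instruction: set devalued outcome utilities to 0, others to 1."""
    state.u[:] = 1.0
    for o in devalued_outcomes:
        state.u[o] = 0.0


def replay_learning(params: TwoSystemParams, trials, contingency: Contingency) -> TwoSystemState:
    """Run the two-system updates over observed learning-phase trials.

    Used to carry a habit/goal state into the devaluation phase when the
    learning-phase behaviour itself was produced by another policy (or by a
    human): the model learns from the emitted actions and obtained rewards.
    """
    params.validate()
    state = TwoSystemState()
    for rec in trials:
        stim = int(rec["stimulus_id"] if isinstance(rec, dict) else rec.stimulus_id)
        resp = rec["response"] if isinstance(rec, dict) else rec.response
        if isinstance(resp, str):
            resp = {"left": 0, "right": 1, "miss": -1}[resp]
        if resp < 0:
            state.C[:] = 0.0
            continue
        reward = contingency.reward(stim, resp)
        learning_phase_step(state, params, stim, int(resp), reward)
    state.C[:] = 0.0  # phase break: stickiness does not carry across phases
    return state


def fit_two_system(trial_log, variant: str = "nhlat", priors=None,
                   n_chains: int = 4, n_iterations: int = 2000, seed: int = 0,
                   effort: str = "thorough"):
    """Hierarchical fit of the two-system model over both task phases.

    Same group/subject hierarchy as the single-system fits; the likelihood
    joins learning-phase choices and devaluation-phase go/no-go responses.
    Returns the posterior draws plus group-difference summaries for all four
    parameters (alpha, w_goal, w_habit, tau).
    """
    from .inference import (build_hierarchical_model, group_difference_summary,
                            sample_posterior)

    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    problem = build_hierarchical_model("two_system", trial_log, priors,
                                       include_devaluation=True, variant=variant)
    draws = sample_posterior(problem, n_chains, n_iterations, seed=seed,
                             effort=effort)
    summaries = {p: group_difference_summary(draws, p) for p in TS_PARAM_NAMES}
    return draws, summaries
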