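"""Structure of the two-phase slips-of-action task.

Phase 1 (appetitive discrimination): 96 trials over 6 stimuli, each with a
single deterministically rewarded response (left/right).  Phase 2 (outcome
devaluation): nine 12-trial blocks of go/no-go responding in which a subset
of outcomes is declared worthless at block onset.

All builders are seed-reproducible and validate their own invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import N_RESPONSES, N_STIMULI

N_LEARNING_TRIALS = 96
N_DEV_BLOCKS = 9
N_DEV_BLOCK_TRIALS = 12

RESPONSE_NAMES = ("left", "right")


class ScheduleError(ValueError):
    """Raised when a requested schedule cannot be counterbalanced."""


@dataclass(frozen=True)
class Contingency:
    """Deterministic stimulus → (correct response, outcome) mapping."""

    correct_response: tuple[int, ...]  # index by stimulus_id, values 0/1
    outcome_id: tuple[int, ...]        # bijection over stimuli

    def __post_init__(self) -> None:
        if len(self.correct_response) != N_STIMULI or len(self.outcome_id) != N_STIMULI:
            raise ValueError("contingency must cover exactly 6 stimuli")
        if not set(self.correct_response) <= set(range(N_RESPONSES)):
            raise ValueError("responses must be 0 (left) or 1 (right)")
        if sorted(self.outcome_id) != list(range(N_STIMULI)):
            raise ValueError("stimulus→outcome mapping must be a bijection")

    def reward(self, stimulus_id: int, response: int) -> int:
        return int(response == self.correct_response[stimulus_id])

    def stimuli_for_outcomes(self, outcomes: frozenset[int]) -> frozenset[int]:
        return frozenset(s for s in range(N_STIMULI) if self.outcome_id[s] in outcomes)


@dataclass(frozen=True)
class LearningSchedule:
    trials: tuple[int, ...]  # stimulus_id per trial

    def __post_init__(self) -> None:
        if len(self.trials) != N_LEARNING_TRIALS:
            raise ValueError(f"learning schedule must have {N_LEARNING_TRIALS} trials")
        counts = np.bincount(self.trials, minlength=N_STIMULI)
        if not np.all(counts == N_LEARNING_TRIALS // N_STIMULI):
            raise ValueError("each stimulus must appear exactly 16 times")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class DevaluationSchedule:
    """Nine blocks of (devalued outcome set, 12 stimulus presentations)."""

    blocks: tuple[tuple[frozenset[int], tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.blocks) != N_DEV_BLOCKS:
            raise ValueError(f"devaluation schedule must have {N_DEV_BLOCKS} blocks")
        counts = np.zeros(N_STIMULI, dtype=int)
        for devalued, trials in self.blocks:
            if len(trials) != N_DEV_BLOCK_TRIALS:
                raise ValueError("each devaluation block must have 12 trials")
            for o in devalued:
                counts[o] += 1
        if counts.max() != counts.min():
            raise ValueError("outcomes must be devalued an equal number of times")

    @property
    def n_trials(self) -> int:
        return sum(len(t) for _, t in self.blocks)


def build_contingency(seed: int) -> Contingency:
    """Random correct responses and a random stimulus→outcome bijection."""
    rng = np.random.default_rng(seed)
    correct = tuple(int(r) for r in rng.integers(0, N_RESPONSES, size=N_STIMULI))
    outcomes = tuple(int(o) for o in rng.permutation(N_STIMULI))
    return Contingency(correct, outcomes)


def _shuffle_max_run(items: np.ndarray, rng: np.random.Generator,
                     max_run: int, max_tries: int = 1000) -> np.ndarray:
    """Shuffle until no value repeats more than ``max_run`` times in a row."""
    for _ in range(max_tries):
        rng.shuffle(items)
        run, ok = 1, True
        for a, b in zip(items, items[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return items
    raise ScheduleError(f"could not satisfy max run length {max_run}")


def build_learning_schedule(contingency: Contingency, seed: int,
                            max_run: int = 3) -> LearningSchedule:
    """96-trial pseudorandom order, 16 presentations per stimulus."""
    rng = np.random.default_rng(seed)
    trials = np.repeat(np.arange(N_STIMULI), N_LEARNING_TRIALS // N_STIMULI)
    trials = _shuffle_max_run(trials, rng, max_run)
    return LearningSchedule(tuple(int(t) for t in trials))


def build_devaluation_schedule(contingency: Contingency,
                               n_devalued_per_block: int = 2,
                               seed: int = 0) -> DevaluationSchedule:
    """Counterbalanced devaluation blocks.

    With the default of 2 devalued outcomes per block, each of the 6 outcomes
    is devalued exactly 3 times over the 9 blocks.  Counterbalancing is exact
    only when ``9 * n_devalued_per_block`` is divisible by 6.
    """
    if not 1 <= n_devalued_per_block <= N_STIMULI - 1:
        raise ScheduleError("n_devalued_per_block must be in [1, 5]")
    total = N_DEV_BLOCKS * n_devalued_per_block
    if total % N_STIMULI:
        raise ScheduleError(
            f"cannot counterbalance {n_devalued_per_block} devalued outcomes "
            f"per block over {N_DEV_BLOCKS} blocks and {N_STIMULI} outcomes")
    rng = np.random.default_rng(seed)
    per_outcome = total // N_STIMULI
    for _ in range(1000):
        # deal each outcome's quota into blocks without within-block repeats
        remaining = {o: per_outcome for o in range(N_STIMULI)}
        blocks: list[frozenset[int]] = []
        ok = True
        for b in range(N_DEV_BLOCKS):
            pool = [o for o, r in remaining.items() if r > 0]
            # prefer outcomes with the largest remaining quota to avoid dead ends
            need = N_DEV_BLOCKS - b
            urgent = [o for o in pool if remaining[o] == need]
            rest = [o for o in pool if remaining[o] < need]
            rng.shuffle(urgent)
            rng.shuffle(rest)
            chosen = (urgent + rest)[:n_devalued_per_block]
            if len(chosen) < n_devalued_per_block:
                ok = False
                break
            for o in chosen:
                remaining[o] -= 1
            blocks.append(frozenset(chosen))
        if ok and all(r == 0 for r in remaining.values()):
            break
    else:
        raise ScheduleError("counterbalancing search failed")
    built = []
    for devalued in blocks:
        trials = np.repeat(np.arange(N_STIMULI), N_DEV_BLOCK_TRIALS // N_STIMULI)
        rng.shuffle(trials)
        built.append((devalued, tuple(int(t) for t in trials)))
    return DevaluationSchedule(tuple(built))


def schedule_to_frame(learning: LearningSchedule,
                      devaluation: DevaluationSchedule,
                      contingency: Contingency):
    """Trial-plan table: phase, block, trial, stimulus_id, devalued_flag."""
    import pandas as pd

    rows = []
    for t, stim in enumerate(learning.trials):
        rows.append(("learning", None, t, stim, None))
    for b, (devalued, trials) in enumerate(devaluation.blocks):
        dev_stims = contingency.stimuli_for_outcomes(devalued)
        for t, stim in enumerate(trials):
            rows.append(("devaluation", b, t, stim, int(stim in dev_stims)))
    return pd.DataFrame(rows, columns=["phase", "block", "trial",
                                       "stimulus_id", "devalued_flag"])
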