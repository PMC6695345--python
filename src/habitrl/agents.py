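"""Synthetic cohorts: subject parameters from a group hierarchy, then
simulated trial-by-trial behaviour for both task phases.

The generator mirrors the inference model exactly: subject parameters are
group mean plus a truncated-normal deviation (truncation, not clipping, so
the generative and inference models coincide), and simulated choices are
drawn from the very probabilities the likelihood modules compute.

Default hyperparameters encode the study conditions: two groups (55 control,
68 CUD after exclusions), a learning-rate deficit of 0.035 on the CUD side,
and no group difference in reinforcement sensitivity or perseveration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import models, task, twosystem
from .models import PARAM_BOUNDS, ModelSpec, RLParams, get_spec
from .task import Contingency, DevaluationSchedule, LearningSchedule
from .twosystem import TwoSystemParams, TwoSystemState

GROUPS = ("control", "cud")

#: columns of the cohort trial log
TRIAL_COLUMNS = ("subject_id", "group", "phase", "block", "trial",
                 "stimulus_id", "response", "reward", "devalued_flag")

N_CONTROL = 55
N_CUD = 68  # 70 recruited, 2 excluded for incomplete data


@dataclass(frozen=True)
class GroupHyperModel:
    """Group-level means per parameter plus shared inter-subject SDs."""

    means: dict[str, float]
    sds: dict[str, float]

    def validate(self) -> None:
        for p, m in self.means.items():
            lo, hi = PARAM_BOUNDS[p]
            if not lo <= m <= hi:
                raise ValueError(f"group mean {p}={m} outside bounds [{lo}, {hi}]")
            sd = self.sds.get(p)
            if sd is None or sd < 0:
                raise ValueError(f"subject SD for {p} must be present and >= 0")


def default_hypers() -> tuple[GroupHyperModel, GroupHyperModel]:
    """Study-condition hyperparameters for the winning three-parameter model.

    Control learning rate 0.15 with the CUD mean 0.035 lower (the credible
    group difference); reinforcement sensitivity near the prior mean of its
    empirical gamma prior; no group difference there or in perseveration.
    The group-level values are calibrated against the published findings
    rather than invented: the learning-rate level sits in the regime where
    a full-size cohort reproduces a *credible* negative CUD difference
    (higher rates saturate the deterministic task so quickly that 96 trials
    cannot resolve the group difference at all), and the perseveration
    level (0.40, CUD 0.02 lower) is set so model comparison reproduces the
    published decisive preference for perseveration-bearing models.  SDs
    sit in the bulk of the half-normal hyperpriors.

    For fractionated-rate variants the reward rate matches the single rate
    and the extinction rate sits 0.05 lower (non-reward is learned from
    more slowly in appetitive discrimination).
    """
    sds = {"alpha": 0.06, "alpha_rew": 0.06, "alpha_ext": 0.06,
           "beta": 1.5, "tau": 0.25}
    control = GroupHyperModel({"alpha": 0.15, "alpha_rew": 0.15, "alpha_ext": 0.10,
                               "beta": 4.2, "tau": 0.40}, dict(sds))
    cud = GroupHyperModel({"alpha": 0.115, "alpha_rew": 0.115, "alpha_ext": 0.065,
                           "beta": 4.2, "tau": 0.38}, dict(sds))
    return control, cud


@dataclass(frozen=True)
class TwoSystemHyper:
    """Group-level two-system means and shared SDs (alpha, w_goal, w_habit, tau)."""

    means: dict[str, float]
    sds: dict[str, float]


def default_two_system_hypers() -> tuple[TwoSystemHyper, TwoSystemHyper]:
    """CUD shows a reduced goal-directed weight, equal habit weight."""
    sds = {"alpha": 0.06, "w_goal": 1.2, "w_habit": 0.5, "tau": 0.3}
    control = TwoSystemHyper({"alpha": 0.15, "w_goal": 4.2, "w_habit": 1.0, "tau": 0.2},
                             dict(sds))
    cud = TwoSystemHyper({"alpha": 0.115, "w_goal": 2.8, "w_habit": 1.0, "tau": 0.3},
                         dict(sds))
    return control, cud


def _truncated_draw(mean: float, sd: float, lo: float, hi: float,
                    size: int, rng: np.random.Generator) -> np.ndarray:
    if sd < 0:
        raise ValueError("subject SD must be >= 0")
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_subject_params(hyper: GroupHyperModel, spec: ModelSpec,
                          n_subjects: int, seed: int) -> list[RLParams]:
    """Draw subject parameters: group mean + truncated-normal deviation."""
    hyper.validate()
    rng = np.random.default_rng(seed)
    draws = {}
    for p in spec.params:
        lo, hi = PARAM_BOUNDS[p]
        draws[p] = _truncated_draw(hyper.means[p], hyper.sds[p], lo, hi, n_subjects, rng)
    return [RLParams.from_dict({p: draws[p][i] for p in spec.params})
            for i in range(n_subjects)]


def simulate_learning_phase(params: RLParams, spec: ModelSpec,
                            schedule: LearningSchedule, contingency: Contingency,
                            seed: int, miss_prob: float = 0.0) -> pd.DataFrame:
    """Simulate phase-1 choices from the exact likelihood-model probabilities."""
    params.validate(spec)
    rng = np.random.default_rng(seed)
    beta = params.beta if spec.has_beta else 0.0
    tau = params.tau if spec.has_tau else 0.0
    state = models.AssociativeState()
    rows = []
    for t, stim in enumerate(schedule.trials):
        if miss_prob and rng.random() < miss_prob:
            rows.append((None, None, "learning", None, t, stim, -1, None, None))
            state.C[:] = 0.0
            continue
        p = models.choice_probabilities(state.V[stim], state.C, beta, tau)
        resp = int(rng.random() < p[1])
        reward = contingency.reward(stim, resp)
        rate = models.select_rate(spec, params, reward)
        state.V[stim, resp] = models.delta_update(state.V[stim, resp], reward, rate)
        state.C[:] = 0.0
        state.C[resp] = 1.0
        rows.append((None, None, "learning", None, t, stim, resp, reward, None))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_devaluation_phase(ts_params: TwoSystemParams,
                               learning_end_state: TwoSystemState,
                               schedule: DevaluationSchedule,
                               contingency: Contingency,
                               variant: str, seed: int) -> pd.DataFrame:
    """Simulate phase-2 go/no-go responses from the two-system model.

    ``learning_end_state`` must come from running the two-system updates over
    the learning phase (see :func:`habitrl.twosystem.replay_learning`).
    Under ``hlat`` habit strengths keep updating within the phase; under
    ``nhlat`` they stay frozen.
    """
    ts_params.validate()
    rng = np.random.default_rng(seed)
    state = learning_end_state.copy()
    rows = []
    for b, (devalued, trials) in enumerate(schedule.blocks):
        twosystem.apply_block_instruction(state, devalued)
        dev_stims = contingency.stimuli_for_outcomes(devalued)
        for t, stim in enumerate(trials):
            p_go = twosystem.devaluation_phase_go_prob(
                state, ts_params, stim, contingency, variant)
            went = bool(rng.random() < p_go)
            twosystem.devaluation_phase_go_prob(
                state, ts_params, stim, contingency, variant,
                update=True, went=went)
            rows.append((None, None, "devaluation", b, t, stim,
                         2 if went else 3, None, int(stim in dev_stims)))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df


def _ts_params_from_hyper(hyper: TwoSystemHyper, n: int, seed: int) -> list[TwoSystemParams]:
    rng = np.random.default_rng(seed)
    draws = {}
    for p in twosystem.TS_PARAM_NAMES:
        lo, hi = PARAM_BOUNDS[p]
        draws[p] = _truncated_draw(hyper.means[p], hyper.sds[p], lo, hi, n, rng)
    return [TwoSystemParams(*(draws[p][i] for p in twosystem.TS_PARAM_NAMES))
            for i in range(n)]


def simulate_cohort(hyper_control: GroupHyperModel | None = None,
                    hyper_cud: GroupHyperModel | None = None,
                    n_control: int = N_CONTROL, n_cud: int = N_CUD,
                    seed: int = 0, spec: ModelSpec | str = "delta_softmax_persev",
                    ts_hypers: tuple[TwoSystemHyper, TwoSystemHyper] | None = None,
                    variant: str = "nhlat",
                    miss_prob: float = 0.0,
                    include_devaluation: bool = True
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full two-group cohort: trial log plus the ground-truth parameter table.

    Learning-phase behaviour comes from the (single-system) likelihood model
    ``spec``; devaluation-phase behaviour comes from the two-system model,
    whose state is built by replaying each subject's own learning-phase
    choices, so habit strengths reflect the behaviour actually emitted.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    if hyper_control is None or hyper_cud is None:
        dc, dd = default_hypers()
        hyper_control = hyper_control or dc
        hyper_cud = hyper_cud or dd
    if ts_hypers is None:
        ts_hypers = default_two_system_hypers()

    root = np.random.default_rng(seed)
    contingency = task.build_contingency(int(root.integers(2**31)))
    logs, truths = [], []
    sid = 0
    for group, hyper, ts_hyper, n in (("control", hyper_control, ts_hypers[0], n_control),
                                      ("cud", hyper_cud, ts_hypers[1], n_cud)):
        subj_params = sample_subject_params(hyper, spec, n, int(root.integers(2**31)))
        ts_list = _ts_params_from_hyper(ts_hyper, n, int(root.integers(2**31)))
        for params, tsp in zip(subj_params, ts_list):
            lsched = task.build_learning_schedule(contingency, int(root.integers(2**31)))
            learn = simulate_learning_phase(params, spec, lsched, contingency,
                                            int(root.integers(2**31)), miss_prob)
            parts = [learn]
            if include_devaluation:
                dsched = task.build_devaluation_schedule(
                    contingency, seed=int(root.integers(2**31)))
                end_state = twosystem.replay_learning(
                    tsp, learn.to_dict("records"), contingency)
                parts.append(simulate_devaluation_phase(
                    tsp, end_state, dsched, contingency, variant,
                    int(root.integers(2**31))))
            df = pd.concat(parts, ignore_index=True)
            df["subject_id"] = sid
            df["group"] = group
            logs.append(df)
            truth = {"subject_id": sid, "group": group}
            truth.update(params.as_dict(spec))
            truth.update({f"ts_{p}": getattr(tsp, p) for p in twosystem.TS_PARAM_NAMES})
            truths.append(truth)
            sid += 1
    return pd.concat(logs, ignore_index=True), pd.DataFrame(truths)


def simulate_two_system_cohort(hyper_control: TwoSystemHyper | None = None,
                               hyper_cud: TwoSystemHyper | None = None,
                               n_control: int = N_CONTROL, n_cud: int = N_CUD,
                               seed: int = 0, variant: str = "nhlat"
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort whose *both* phases are generated by the two-system model.

    Used for two-system parameter-recovery studies: the learning phase is
    simulated from the two-system softmax itself (not the single-system
    model), so the fitted model is exactly the generating model.
    """
    if hyper_control is None or hyper_cud is None:
        dc, dd = default_two_system_hypers()
        hyper_control = hyper_control or dc
        hyper_cud = hyper_cud or dd
    root = np.random.default_rng(seed)
    contingency = task.build_contingency(int(root.integers(2**31)))
    logs, truths = [], []
    sid = 0
    for group, hyper, n in (("control", hyper_control, n_control),
                            ("cud", hyper_cud, n_cud)):
        ts_list = _ts_params_from_hyper(hyper, n, int(root.integers(2**31)))
        for tsp in ts_list:
            rng = np.random.default_rng(int(root.integers(2**31)))
            lsched = task.build_learning_schedule(contingency, int(root.integers(2**31)))
            state = TwoSystemState()
            rows = []
            for t, stim in enumerate(lsched.trials):
                p = twosystem.learning_phase_choice_prob(state, tsp, stim, contingency)
                resp = int(rng.random() < p[1])
                reward = contingency.reward(stim, resp)
                twosystem.learning_phase_step(state, tsp, stim, resp, reward)
                rows.append((sid, group, "learning", None, t, stim, resp, reward, None))
            learn = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
            state.C[:] = 0.0
            dsched = task.build_devaluation_schedule(
                contingency, seed=int(root.integers(2**31)))
            dev = simulate_devaluation_phase(tsp, state, dsched, contingency,
                                             variant, int(root.integers(2**31)))
            dev["subject_id"] = sid
            dev["group"] = group
            logs.append(pd.concat([learn, dev], ignore_index=True))
            truth = {"subject_id": sid, "group": group}
            truth.update({p: getattr(tsp, p) for p in twosystem.TS_PARAM_NAMES})
            truths.append(truth)
            sid += 1
    return pd.concat(logs, ignore_index=True), pd.DataFrame(truths)
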