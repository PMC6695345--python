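"""Trial-by-trial reinforcement-learning likelihoods for the discrimination phase.

The behavioural model is a Rescorla–Wagner delta rule over stimulus–response
associative strengths, combined with a softmax choice rule that admits a
perseveration ("stickiness") term:

    V[t+1](s, a) = V[t](s, a) + alpha * (R[t] - V[t](s, a))
    p(a | s, t)  = exp(beta * V[t](s, a) + tau * C[t](a)) / sum_k exp(...)

where ``C[t](a)`` indicates whether response ``a`` was emitted on the previous
trial.  Model variants differ in whether the learning rate is fractionated
into a reward rate (``alpha_rew``, applied on rewarded trials) and an
extinction rate (``alpha_ext``, applied on non-rewarded trials), and in which
of ``beta`` / ``tau`` are free.  A parameter-free random-choice baseline
(p = 0.5 for each response) closes the family.

Everything here is a pure, deterministic function of data and parameters;
simulation lives in :mod:`habitrl.agents` and inference in
:mod:`habitrl.inference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

N_STIMULI = 6
N_RESPONSES = 2
LOG_HALF = math.log(0.5)

#: canonical parameter order used throughout the package
PARAM_NAMES = ("alpha", "alpha_rew", "alpha_ext", "beta", "tau")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family: a named set of free parameters."""

    name: str
    params: tuple[str, ...]
    fractionated_rates: bool = False
    has_beta: bool = False
    has_tau: bool = False
    is_random_baseline: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)} in spec {self.name!r}")
        if self.fractionated_rates:
            if "alpha" in self.params or not {"alpha_rew", "alpha_ext"} <= set(self.params):
                raise ValueError("fractionated spec must carry alpha_rew/alpha_ext and no alpha")
        if self.is_random_baseline and self.params:
            raise ValueError("random baseline has no free parameters")

    @property
    def n_params(self) -> int:
        return len(self.params)


def model_registry() -> list[ModelSpec]:
    """The seven model variants compared in the analysis.

    Listed with the winning three-parameter model first: single learning
    rate, reinforcement sensitivity and perseveration.  The last entry is
    the random-choice baseline.
    """
    return [
        ModelSpec("delta_softmax_persev", ("alpha", "beta", "tau"),
                  has_beta=True, has_tau=True),
        ModelSpec("dualrate_softmax_persev", ("alpha_rew", "alpha_ext", "beta", "tau"),
                  fractionated_rates=True, has_beta=True, has_tau=True),
        ModelSpec("dualrate_softmax", ("alpha_rew", "alpha_ext", "beta"),
                  fractionated_rates=True, has_beta=True),
        ModelSpec("delta_softmax", ("alpha", "beta"), has_beta=True),
        ModelSpec("dualrate_persev", ("alpha_rew", "alpha_ext", "tau"),
                  fractionated_rates=True, has_tau=True),
        ModelSpec("delta_persev", ("alpha", "tau"), has_tau=True),
        ModelSpec("random", (), is_random_baseline=True),
    ]


def get_spec(name: str) -> ModelSpec:
    for spec in model_registry():
        if spec.name == name:
            return spec
    raise KeyError(f"no model named {name!r}; known: {[s.name for s in model_registry()]}")


@dataclass
class RLParams:
    """A subject's parameter point for one model variant.

    ``alpha``-type rates live in [0, 1]; ``beta`` is non-negative; ``tau`` is
    unbounded (negative values express a tendency to switch responses).
    Only the parameters of the owning variant should be set.
    """

    alpha: float | None = None
    alpha_rew: float | None = None
    alpha_ext: float | None = None
    beta: float | None = None
    tau: float | None = None

    def validate(self, spec: ModelSpec) -> None:
        for name in spec.params:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"spec {spec.name!r} requires parameter {name!r}")
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite")
            if name.startswith("alpha") and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
            if name == "beta" and value < 0.0:
                raise ValueError(f"beta={value} must be >= 0")
        for name in set(PARAM_NAMES) - set(spec.params):
            if getattr(self, name) is not None:
                raise ValueError(f"parameter {name!r} not part of spec {spec.name!r}")

    def as_dict(self, spec: ModelSpec) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in spec.params}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "RLParams":
        return cls(**{k: float(v) for k, v in values.items()})


PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "alpha_rew": (0.0, 1.0),
    "alpha_ext": (0.0, 1.0),
    "beta": (0.0, np.inf),
    "tau": (-np.inf, np.inf),
    # expression weights of the two-system model share beta's support
    "w_goal": (0.0, np.inf),
    "w_habit": (0.0, np.inf),
}


@dataclass
class AssociativeState:
    """Evolving V table plus the previous-choice indicator.

    ``V`` maps (stimulus, response) to associative strength; ``C`` is the
    global previous-response indicator (at most one entry set).
    """

    V: np.ndarray = field(default_factory=lambda: np.zeros((N_STIMULI, N_RESPONSES)))
    C: np.ndarray = field(default_factory=lambda: np.zeros(N_RESPONSES))


def delta_update(v: float, reward: float, rate: float) -> float:
    """One Rescorla–Wagner step: move ``v`` toward ``reward`` by ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"learning rate {rate} outside [0, 1]")
    return v + rate * (reward - v)


def select_rate(spec: ModelSpec, params: RLParams, reward: int) -> float:
    """Learning rate applicable to this trial's outcome under ``spec``."""
    if spec.fractionated_rates:
        rate = params.alpha_rew if reward else params.alpha_ext
        which = "alpha_rew" if reward else "alpha_ext"
    else:
        rate, which = params.alpha, "alpha"
    if rate is None:
        raise ValueError(f"spec {spec.name!r} needs {which} but it is unset")
    return rate


def choice_probabilities(V_s: Sequence[float], C: Sequence[float],
                         beta: float, tau: float) -> np.ndarray:
    """Softmax over ``beta * V + tau * C``, log-sum-exp stabilised."""
    V_s = np.asarray(V_s, dtype=float)
    C = np.asarray(C, dtype=float)
    if not (np.all(np.isfinite(V_s)) and np.all(np.isfinite(C))
            and np.isfinite(beta) and np.isfinite(tau)):
        raise ValueError("non-finite inputs to choice_probabilities")
    drive = beta * V_s + tau * C
    drive -= drive.max()
    ex = np.exp(drive)
    return ex / ex.sum()


def subject_log_likelihood(spec: ModelSpec, params: RLParams, trials) -> float:
    """Summed log probability of a subject's discrimination-phase choices.

    ``trials`` is an iterable of records with attributes (or dict keys)
    ``trial``, ``stimulus_id``, ``response`` (0=left, 1=right, -1=miss) and
    ``reward``; it must be sorted by trial index and contain only
    learning-phase rows.  Miss trials contribute no likelihood and do not
    update V, but they clear the perseveration indicator.
    """
    rows = _coerce_rows(trials)
    if spec.is_random_baseline:
        return sum(1 for _, _, resp, _ in rows if resp >= 0) * LOG_HALF
    params.validate(spec)
    beta = params.beta if spec.has_beta else 0.0
    tau = params.tau if spec.has_tau else 0.0

    state = AssociativeState()
    total = 0.0
    for _, stim, resp, reward in rows:
        if resp < 0:  # miss: no update, no likelihood, sticky trace cleared
            state.C[:] = 0.0
            continue
        p = choice_probabilities(state.V[stim], state.C, beta, tau)
        total += math.log(p[resp])
        rate = select_rate(spec, params, reward)
        state.V[stim, resp] = delta_update(state.V[stim, resp], reward, rate)
        state.C[:] = 0.0
        state.C[resp] = 1.0
    return total


def _coerce_rows(trials) -> list[tuple[int, int, int, int]]:
    rows = []
    for rec in trials:
        get = rec.get if isinstance(rec, Mapping) else lambda k, r=rec: getattr(r, k)
        phase = get("phase")
        if phase not in (None, "learning"):
            raise ValueError("subject_log_likelihood accepts learning-phase rows only")
        resp = get("response")
        if isinstance(resp, str):
            resp = {"left": 0, "right": 1, "miss": -1}[resp]
        reward = get("reward")
        reward = -1 if reward is None else int(reward)
        rows.append((int(get("trial")), int(get("stimulus_id")), int(resp), reward))
    for a, b in zip(rows, rows[1:]):
        if b[0] <= a[0]:
            raise ValueError("trials must be sorted by increasing trial index")
    for t, stim, resp, reward in rows:
        if resp >= 0 and reward not in (0, 1):
            raise ValueError(f"trial {t}: reward must be 0/1 on non-miss learning trials")
    return rows
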