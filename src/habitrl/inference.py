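"""Hierarchical Bayesian inference for the trial-by-trial learning models.

The hierarchy follows the study's estimation scheme.  For each free
parameter there is one group-level mean per group (the primary measures of
interest) and one inter-subject SD shared across groups; each subject's
parameter is its group mean plus a normal deviation truncated to the
parameter's support.  Group-mean priors: Beta(1.1, 1.1) for learning-rate
parameters, Gamma(4.82, scale 0.88) for reinforcement sensitivity (and for
the two-system expression weights, which play the same role), Normal(0, 1)
for perseveration.  SD hyperpriors: Half-Normal(0.17) for rates and
perseveration, Half-Normal(2) for sensitivity-type weights.

Sampling is by adaptive single-site Metropolis-within-Gibbs (numba kernel in
:mod:`habitrl._kernels`); the contract is seeded reproducibility plus the
split-chain R-hat < 1.1 convergence gate, with posterior correctness checked
against conjugate closed forms in the test-suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .models import ModelSpec, get_spec
from .twosystem import TS_PARAM_NAMES

_KIND_OF = {
    "alpha": _kernels.KIND_ALPHA, "alpha_rew": _kernels.KIND_ALPHA,
    "alpha_ext": _kernels.KIND_ALPHA,
    "beta": _kernels.KIND_BETA, "w_goal": _kernels.KIND_BETA,
    "w_habit": _kernels.KIND_BETA,
    "tau": _kernels.KIND_TAU,
}
_ROLE_OF = {
    "alpha": _kernels.ROLE_ALPHA, "alpha_rew": _kernels.ROLE_AREW,
    "alpha_ext": _kernels.ROLE_AEXT, "beta": _kernels.ROLE_BETA,
    "tau": _kernels.ROLE_TAU,
}


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the group-level priors (see module docstring)."""

    alpha_beta: tuple[float, float] = (1.1, 1.1)
    beta_gamma: tuple[float, float] = (4.82, 0.88)  # shape, scale
    tau_normal: tuple[float, float] = (0.0, 1.0)
    sd_halfnormal_alpha: float = 0.17
    sd_halfnormal_tau: float = 0.17
    sd_halfnormal_beta: float = 2.0

    def mean_prior(self, param: str) -> tuple[float, float]:
        kind = _KIND_OF[param]
        if kind == _kernels.KIND_ALPHA:
            return self.alpha_beta
        if kind == _kernels.KIND_BETA:
            return self.beta_gamma
        return self.tau_normal

    def sd_scale(self, param: str) -> float:
        kind = _KIND_OF[param]
        if kind == _kernels.KIND_ALPHA:
            return self.sd_halfnormal_alpha
        if kind == _kernels.KIND_BETA:
            return self.sd_halfnormal_beta
        return self.sd_halfnormal_tau


@dataclass
class HierarchicalProblem:
    """A fully-assembled inference problem (model + packed data + priors)."""

    model_name: str
    param_names: tuple[str, ...]
    model_kind: int          # 0 single-system, 1 two-system
    fractionated: bool
    hlat: bool
    priors: PriorSpec
    group_names: tuple[str, ...]
    subject_ids: list
    group: np.ndarray        # (S,) int
    stim1: np.ndarray        # (S, T1) int32
    choice1: np.ndarray
    reward1: np.ndarray
    n1: np.ndarray
    stim2: np.ndarray
    go2: np.ndarray
    dev2: np.ndarray
    n2: np.ndarray
    corr: np.ndarray         # (6,) learned correct response per stimulus
    excluded: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def kernel_args(self):
        kinds = np.array([_KIND_OF[p] for p in self.param_names], dtype=np.int64)
        roles = np.array([_ROLE_OF.get(p, 0) for p in self.param_names], dtype=np.int64)
        prior_a = np.array([self.priors.mean_prior(p)[0] for p in self.param_names])
        prior_b = np.array([self.priors.mean_prior(p)[1] for p in self.param_names])
        sd_scale = np.array([self.priors.sd_scale(p) for p in self.param_names])
        return (self.model_kind, roles, self.fractionated, self.hlat,
                kinds, prior_a, prior_b, sd_scale,
                self.group, self.stim1, self.choice1, self.reward1, self.n1,
                self.stim2, self.go2, self.dev2, self.n2, self.corr)

    def quantity_names(self) -> list[str]:
        names = [f"mu[{g},{p}]" for g in self.group_names for p in self.param_names]
        names += [f"sigma[{p}]" for p in self.param_names]
        names += [f"theta[{sid},{p}]" for sid in self.subject_ids
                  for p in self.param_names]
        return names


@dataclass
class PosteriorDraws:
    """Posterior samples: array (chains, iterations, quantities) + names."""

    array: np.ndarray
    names: list[str]
    problem: HierarchicalProblem | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.array[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def group_mean_difference(self, parameter: str) -> np.ndarray:
        """Per-draw (CUD − control) group-mean difference, pooled over chains."""
        pr = self.problem
        if pr is None or pr.n_groups != 2:
            raise ValueError("group difference requires a two-group fit")
        g0, g1 = pr.group_names  # (control, cud) by convention
        return (self.pooled(f"mu[{g1},{parameter}]")
                - self.pooled(f"mu[{g0},{parameter}]"))

    def to_frame(self) -> pd.DataFrame:
        flat = self.array.reshape(-1, self.array.shape[2])
        df = pd.DataFrame(flat, columns=self.names)
        idx = np.arange(flat.shape[0])
        df.insert(0, "iteration", idx % self.array.shape[1])
        df.insert(0, "chain", idx // self.array.shape[1])
        return df


@dataclass
class PosteriorSummary:
    quantity: str
    mean: float
    hdi_low: float
    hdi_high: float
    pnz: float
    rhat: float
    credible: bool  # 95% HDI excludes zero


def infer_correct_responses(trial_log: pd.DataFrame) -> np.ndarray:
    """Recover the deterministic contingency from rewarded learning trials."""
    learn = trial_log[trial_log["phase"] == "learning"]
    rewarded = learn[(learn["reward"] == 1) & (learn["response"].isin([0, 1]))]
    corr = np.full(6, -1, dtype=np.int64)
    for s, sub in rewarded.groupby("stimulus_id"):
        corr[int(s)] = int(sub["response"].mode().iloc[0])
    if (corr < 0).any():
        missing = np.where(corr < 0)[0].tolist()
        raise ValueError(f"no rewarded trials observed for stimuli {missing}; "
                         "cannot recover the contingency")
    return corr


def build_hierarchical_model(spec: ModelSpec | str, trial_log: pd.DataFrame,
                             priors: PriorSpec | None = None,
                             include_devaluation: bool = False,
                             variant: str = "nhlat",
                             param_names: tuple[str, ...] | None = None
                             ) -> HierarchicalProblem:
    """Assemble the hierarchical inference problem from a cohort trial log.

    With ``include_devaluation=False`` (the default, used for the
    single-system model family) only learning-phase rows enter the
    likelihood.  Subjects with zero usable trials are excluded with a
    warning.  The random baseline has nothing to fit and is rejected.
    """
    if isinstance(spec, str) and spec != "two_system":
        spec = get_spec(spec)
    priors = priors or PriorSpec()
    if spec == "two_system":
        model_name, names = "two_system", tuple(TS_PARAM_NAMES)
        model_kind, frac = 1, False
    else:
        if spec.is_random_baseline:
            raise ValueError("the random baseline has no free parameters to fit")
        model_name, names = spec.name, tuple(spec.params)
        model_kind, frac = 0, spec.fractionated_rates
    if param_names is not None:
        names = tuple(param_names)

    df = trial_log.copy()
    group_names = tuple(pd.unique(df["group"]))
    if not 1 <= len(group_names) <= 2:
        raise ValueError("expected one or two groups in the trial log")
    if set(group_names) == {"control", "cud"}:
        group_names = ("control", "cud")  # canonical order for differences
    subjects, excluded = [], []
    for sid, sub in df.groupby("subject_id", sort=True):
        learn = sub[sub["phase"] == "learning"].sort_values("trial")
        usable = (learn["response"] >= 0).sum()
        if usable == 0:
            excluded.append(sid)
            continue
        subjects.append((sid, sub))
    if excluded:
        warnings.warn(f"excluding subjects with no usable trials: {excluded}")
    S = len(subjects)
    per_group = pd.Series([sub["group"].iloc[0] for _, sub in subjects]).value_counts()
    if len(group_names) == 2 and (per_group.reindex(list(group_names)).fillna(0) < 2).any():
        raise ValueError("need at least 2 usable subjects per group")

    T1 = max(len(sub[sub["phase"] == "learning"]) for _, sub in subjects)
    stim1 = np.zeros((S, T1), dtype=np.int64)
    choice1 = np.full((S, T1), -1, dtype=np.int64)
    reward1 = np.zeros((S, T1), dtype=np.int64)
    n1 = np.zeros(S, dtype=np.int64)
    if include_devaluation:
        T2 = max(len(sub[sub["phase"] == "devaluation"]) for _, sub in subjects)
        T2 = max(T2, 1)
    else:
        T2 = 1
    stim2 = np.zeros((S, T2), dtype=np.int64)
    go2 = np.full((S, T2), -1, dtype=np.int64)
    dev2 = np.zeros((S, T2), dtype=np.int64)
    n2 = np.zeros(S, dtype=np.int64)

    group_idx = np.zeros(S, dtype=np.int64)
    ids = []
    for i, (sid, sub) in enumerate(subjects):
        ids.append(sid)
        group_idx[i] = group_names.index(sub["group"].iloc[0])
        learn = sub[sub["phase"] == "learning"].sort_values("trial")
        k = len(learn)
        n1[i] = k
        stim1[i, :k] = learn["stimulus_id"].to_numpy()
        choice1[i, :k] = learn["response"].to_numpy()
        rew = learn["reward"].to_numpy()
        reward1[i, :k] = np.where(pd.isna(rew), 0, rew).astype(np.int64)
        if include_devaluation:
            dev = sub[sub["phase"] == "devaluation"].sort_values(["block", "trial"])
            k2 = len(dev)
            n2[i] = k2
            if k2:
                stim2[i, :k2] = dev["stimulus_id"].to_numpy()
                resp = dev["response"].to_numpy()
                # 2 = go, 3 = no-go in the integer coding; -1 stays miss
                go2[i, :k2] = np.where(resp == 2, 1, np.where(resp == 3, 0, -1))
                dev2[i, :k2] = dev["devalued_flag"].to_numpy().astype(np.int64)

    corr = (infer_correct_responses(trial_log) if include_devaluation
            else np.zeros(6, dtype=np.int64))
    return HierarchicalProblem(
        model_name=model_name, param_names=names, model_kind=model_kind,
        fractionated=frac, hlat=(variant == "hlat"), priors=priors,
        group_names=group_names, subject_ids=ids, group=group_idx,
        stim1=stim1, choice1=choice1, reward1=reward1, n1=n1,
        stim2=stim2, go2=go2, dev2=dev2, n2=n2, corr=corr,
        excluded=excluded)


def _initial_state(problem: HierarchicalProblem, rng: np.random.Generator):
    """Overdispersed chain starting point drawn around the priors' bulk."""
    G, P, S = problem.n_groups, problem.n_params, problem.n_subjects
    mu0 = np.empty((G, P))
    sigma0 = np.empty(P)
    for j, p in enumerate(problem.param_names):
        kind = _KIND_OF[p]
        for g in range(G):
            if kind == _kernels.KIND_ALPHA:
                mu0[g, j] = rng.uniform(0.15, 0.85)
            elif kind == _kernels.KIND_BETA:
                mu0[g, j] = rng.uniform(1.0, 8.0)
            else:
                mu0[g, j] = rng.normal(0.0, 0.5)
        sigma0[j] = problem.priors.sd_scale(p) * rng.uniform(0.3, 1.2)
    theta0 = np.empty((S, P))
    for i in range(S):
        for j, p in enumerate(problem.param_names):
            kind = _KIND_OF[p]
            m = mu0[problem.group[i], j]
            x = m + rng.normal(0.0, 0.3 * sigma0[j])
            if kind == _kernels.KIND_ALPHA:
                x = min(max(x, 1e-3), 1 - 1e-3)
            elif kind == _kernels.KIND_BETA:
                x = max(x, 1e-3)
            theta0[i, j] = x
    return mu0, sigma0, theta0


def sample_posterior(problem: HierarchicalProblem, n_chains: int = 4,
                     n_iterations: int = 2000, n_warmup: int | None = None,
                     seed: int = 0, effort: str = "thorough") -> PosteriorDraws:
    """Run MCMC chains from distinct seeded starting points.

    ``n_iterations`` is the total per-chain count; the first ``n_warmup``
    (default: 30%, where step-size adaptation has long settled — discarding
    more only starves the diagnostics of draws) are adaptation and are
    discarded.  Identical seed and configuration give identical draws.
    ``effort`` selects the mixing-move schedule: "thorough" (default)
    carries the full interweaving needed for large cohorts; "fast" is
    adequate for small-cohort fits such as model-comparison sweeps.
    """
    if effort not in ("thorough", "fast"):
        raise ValueError("effort must be 'thorough' or 'fast'")
    if n_warmup is None:
        n_warmup = min(max(200, int(0.3 * n_iterations)),
                       max(1, n_iterations // 2))
    if not 0 < n_warmup < n_iterations:
        raise ValueError("need 0 < n_warmup < n_iterations")
    if n_chains < 2:
        warnings.warn("fewer than 2 chains: R-hat diagnostics are undefined")
    args = problem.kernel_args()
    chain_seeds = np.random.SeedSequence(seed).generate_state(n_chains) % (2**31 - 1)
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng(int(chain_seeds[c]))
        mu0, sigma0, theta0 = _initial_state(problem, rng)
        draws = _kernels.run_chain(int(chain_seeds[c]), n_iterations, n_warmup,
                                   *args, mu0, sigma0, theta0,
                                   1 if effort == "thorough" else 0)
        chains.append(draws)
    arr = np.stack(chains)
    return PosteriorDraws(arr, problem.quantity_names(), problem, seed,
                          meta={"n_chains": n_chains, "n_iterations": n_iterations,
                                "n_warmup": n_warmup, "effort": effort,
                                "beta_prior_interpretation": "shape/scale"})


def rhat(draws: PosteriorDraws | np.ndarray, quantity: str | None = None) -> float:
    """Split-chain potential scale reduction factor.

    Accepts a PosteriorDraws plus quantity name, or a raw (chains, iters)
    array.  Constant draws give NaN with a warning.
    """
    x = draws.get(quantity) if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("rhat needs >= 2 chains of >= 10 iterations")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0.0:
        warnings.warn("constant draws: R-hat undefined")
        return math.nan
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("hdi needs at least 100 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def pnz(diff_draws: np.ndarray) -> float:
    """Posterior mass on the dominant sign of a difference."""
    d = np.asarray(diff_draws)
    p_pos = float(np.mean(d > 0))
    return max(p_pos, 1.0 - p_pos)


def group_difference_summary(draws: PosteriorDraws, parameter: str) -> PosteriorSummary:
    """Posterior of the (CUD − control) group-mean difference for one parameter."""
    if parameter not in draws.problem.param_names:
        raise ValueError(f"parameter {parameter!r} not in model "
                         f"{draws.problem.model_name!r}")
    diff = draws.group_mean_difference(parameter)
    g0, g1 = draws.problem.group_names
    per_chain = (draws.get(f"mu[{g1},{parameter}]")
                 - draws.get(f"mu[{g0},{parameter}]"))
    lo, hi = hdi(diff)
    return PosteriorSummary(
        quantity=f"diff[{parameter}]", mean=float(diff.mean()),
        hdi_low=lo, hdi_high=hi, pnz=pnz(diff),
        rhat=rhat(per_chain), credible=not (lo <= 0.0 <= hi))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, 95% HDI, and R-hat for every monitored quantity."""
    rows = []
    for i, name in enumerate(draws.names):
        x = draws.array[:, :, i]
        lo, hi = hdi(x.ravel())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = rhat(x)
        rows.append((name, x.mean(), lo, hi, r))
    df = pd.DataFrame(rows, columns=["quantity", "mean", "hdi_low", "hdi_high", "rhat"])
    if draws.problem is not None and draws.problem.n_groups == 2:
        for p in draws.problem.param_names:
            s = group_difference_summary(draws, p)
            df.loc[len(df)] = (s.quantity, s.mean, s.hdi_low, s.hdi_high, s.rhat)
    return df


@dataclass
class ConvergenceReport:
    threshold: float
    rhats: dict[str, float]
    failures: list[str]

    @property
    def passed(self) -> bool:
        return not self.failures

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhats.values() if not math.isnan(v)]
        return max(vals) if vals else math.nan


def convergence_gate(draws: PosteriorDraws, threshold: float = 1.1) -> ConvergenceReport:
    """R-hat for every monitored quantity (incl. group contrasts); pass iff all < threshold."""
    rhats: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(draws.names):
            rhats[name] = rhat(draws.array[:, :, i])
        if draws.problem is not None and draws.problem.n_groups == 2:
            g0, g1 = draws.problem.group_names
            for p in draws.problem.param_names:
                per_chain = (draws.get(f"mu[{g1},{p}]") - draws.get(f"mu[{g0},{p}]"))
                rhats[f"diff[{p}]"] = rhat(per_chain)
    failures = [k for k, v in rhats.items() if not (v < threshold)]
    return ConvergenceReport(threshold, rhats, failures)


def sample_prior(spec: ModelSpec | str, priors: PriorSpec | None = None,
                 n_chains: int = 4, n_iterations: int = 20000,
                 seed: int = 0) -> PosteriorDraws:
    """Sample the hierarchy with an empty likelihood (prior predictive check)."""
    if isinstance(spec, str) and spec != "two_system":
        spec = get_spec(spec)
    empty = pd.DataFrame(columns=["subject_id", "group", "phase", "block", "trial",
                                  "stimulus_id", "response", "reward", "devalued_flag"])
    priors = priors or PriorSpec()
    names = tuple(TS_PARAM_NAMES) if spec == "two_system" else tuple(spec.params)
    problem = HierarchicalProblem(
        model_name="prior", param_names=names, model_kind=0,
        fractionated=False, hlat=False, priors=priors,
        group_names=("control", "cud"), subject_ids=[],
        group=np.zeros(0, dtype=np.int64),
        stim1=np.zeros((0, 1), dtype=np.int64),
        choice1=np.zeros((0, 1), dtype=np.int64),
        reward1=np.zeros((0, 1), dtype=np.int64), n1=np.zeros(0, dtype=np.int64),
        stim2=np.zeros((0, 1), dtype=np.int64), go2=np.zeros((0, 1), dtype=np.int64),
        dev2=np.zeros((0, 1), dtype=np.int64), n2=np.zeros(0, dtype=np.int64),
        corr=np.zeros(6, dtype=np.int64))
    return sample_posterior(problem, n_chains, n_iterations, seed=seed)


def sample_logpdf(logpdf, x0: np.ndarray, n_iterations: int = 10000,
                  n_warmup: int | None = None, step: float = 0.5,
                  seed: int = 0, n_chains: int = 4) -> np.ndarray:
    """Generic seeded random-walk Metropolis for small (toy) problems.

    Returns draws of shape (n_chains, n_iterations - n_warmup, dim).  Used by
    validation studies against conjugate closed forms; not for the
    hierarchical models (those use the compiled kernel).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if n_warmup is None:
        n_warmup = n_iterations // 2
    dim = x0.size
    out = np.empty((n_chains, n_iterations - n_warmup, dim))
    seeds = np.random.SeedSequence(seed).generate_state(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(int(seeds[c]))
        x = x0 + rng.normal(0, step, dim)
        lp = logpdf(x)
        sc = step
        acc = 0
        for it in range(n_iterations):
            xp = x + sc * rng.normal(size=dim)
            lpp = logpdf(xp)
            if lpp - lp >= 0 or rng.random() < math.exp(lpp - lp):
                x, lp = xp, lpp
                acc += 1
            if it < n_warmup and (it + 1) % 50 == 0:
                sc *= math.exp(0.3 if acc / 50 > 0.3 else -0.3)
                acc = 0
            if it >= n_warmup:
                out[c, it - n_warmup] = x
    return out
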