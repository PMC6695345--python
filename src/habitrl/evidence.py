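"""Marginal likelihoods by bridge sampling and Bayesian model comparison.

The marginal likelihood P(D | M) integrates the likelihood over the model's
prior and is estimated here with the iterative optimal-bridge identity of
Meng & Wong: posterior draws are mapped to unconstrained coordinates, half
are used to moment-match a multivariate-normal proposal, and the bridge
iteration runs on the other half together with fresh proposal draws.
Marginal likelihoods combine with equal prior model probabilities into
posterior model probabilities; Bayes factors between ranked models are
reported in log10 (evidence values themselves in natural log).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from .inference import (HierarchicalProblem, PosteriorDraws, PriorSpec,
                        build_hierarchical_model, convergence_gate,
                        sample_posterior, _KIND_OF)
from .models import LOG_HALF, ModelSpec, get_spec, model_registry


class BridgeError(RuntimeError):
    pass


def bridge_log_marginal_likelihood(samples: np.ndarray, log_unnormalized_posterior,
                                   seed: int = 0, rel_tol: float = 1e-10,
                                   max_iter: int = 1000,
                                   split: float = 0.5) -> tuple[float, float]:
    """Natural-log marginal likelihood of a density given posterior samples.

    ``samples``: (N, D) posterior draws on *unconstrained* coordinates.
    ``log_unnormalized_posterior``: vectorised callable mapping an (n, D)
    array to the n log densities (log prior + log likelihood + log Jacobian).
    Returns ``(log_Z, mc_error)`` where ``mc_error`` is an approximate
    Monte-Carlo standard error of log_Z (independent-draw approximation).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    N, D = X.shape
    if N < 40:
        raise BridgeError("too few posterior draws for bridge sampling")
    n_fit = int(N * split)
    fit, est = X[:n_fit], X[n_fit:]
    m = fit.mean(axis=0)
    cov = np.cov(fit, rowvar=False).reshape(D, D) + 1e-10 * np.eye(D)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise BridgeError("proposal covariance is singular") from exc

    rng = np.random.default_rng(seed)
    N1 = est.shape[0]
    N2 = N1
    prop = m + rng.standard_normal((N2, D)) @ L.T

    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    inv = np.linalg.inv(cov)

    def log_g(pts):
        d = pts - m
        return -0.5 * (np.einsum("ij,jk,ik->i", d, inv, d)
                       + D * math.log(2 * math.pi) + logdet)

    l1 = log_unnormalized_posterior(est) - log_g(est)    # posterior draws
    l2 = log_unnormalized_posterior(prop) - log_g(prop)  # proposal draws
    if not np.all(np.isfinite(l1)):
        bad = int(np.sum(~np.isfinite(l1)))
        raise BridgeError(f"{bad} posterior draws have non-finite density")
    keep = np.isfinite(l2)
    l2 = l2[keep]
    N2 = l2.size
    if N2 < N1 // 2:
        raise BridgeError("proposal overlaps the posterior too poorly")

    # Meng-Wong iteration, entirely in log space so heavy likelihood tails
    # cannot overflow: with shifted weights l~ = l - lstar,
    #   num = mean_i exp(l2_i - lse(log s1 + l2_i, log s2 + log r))
    #   den = mean_j exp(     - lse(log s1 + l1_j, log s2 + log r))
    s1 = N1 / (N1 + N2)
    s2 = N2 / (N1 + N2)
    lstar = float(np.median(l1))
    t1 = l1 - lstar
    t2 = l2 - lstar
    log_s1 = math.log(s1)
    log_s2 = math.log(s2)
    log_r = 0.0
    trace = []
    for _ in range(max_iter):
        d2 = np.logaddexp(log_s1 + t2, log_s2 + log_r)
        d1 = np.logaddexp(log_s1 + t1, log_s2 + log_r)
        log_num = logsumexp(t2 - d2) - math.log(N2)
        log_den = logsumexp(-d1) - math.log(N1)
        log_r_new = log_num - log_den
        trace.append(log_r_new)
        if abs(log_r_new - log_r) < rel_tol * max(1.0, abs(log_r_new)):
            log_r = log_r_new
            break
        log_r = log_r_new
    else:
        raise BridgeError(f"bridge iteration did not converge; trace tail "
                          f"{trace[-5:]}")
    log_z = log_r + lstar

    f2 = np.exp(t2 - np.logaddexp(log_s1 + t2, log_s2 + log_r))
    f1 = np.exp(-np.logaddexp(log_s1 + t1, log_s2 + log_r))
    re2 = (np.var(f2) / (N2 * np.mean(f2) ** 2)
           + np.var(f1) / (N1 * np.mean(f1) ** 2))
    return log_z, math.sqrt(re2)


def draws_to_unconstrained(draws: PosteriorDraws) -> np.ndarray:
    """Map pooled hierarchical draws to the kernel's unconstrained layout."""
    pr = draws.problem
    X = draws.array.reshape(-1, draws.array.shape[2]).copy()
    col = 0
    kinds = [_KIND_OF[p] for p in pr.param_names]
    P = pr.n_params
    for g in range(pr.n_groups):
        for j in range(P):
            X[:, col] = _unc_col(X[:, col], kinds[j])
            col += 1
    for j in range(P):
        X[:, col] = np.log(X[:, col])  # sigma
        col += 1
    for s in range(pr.n_subjects):
        for j in range(P):
            X[:, col] = _unc_col(X[:, col], kinds[j])
            col += 1
    return X


def _unc_col(x, kind):
    if kind == _kernels.KIND_ALPHA:
        x = np.clip(x, 1e-12, 1 - 1e-12)
        return np.log(x / (1 - x))
    if kind == _kernels.KIND_BETA:
        return np.log(np.maximum(x, 1e-300))
    return x


def evidence_from_fit(draws: PosteriorDraws, seed: int = 0,
                      max_draws: int = 4000,
                      require_convergence: bool = True) -> tuple[float, float]:
    """Bridge-sampled log marginal likelihood of a fitted hierarchical model."""
    report = convergence_gate(draws)
    if require_convergence and not report.passed:
        raise BridgeError(f"fit failed the convergence gate: {report.failures}")
    X = draws_to_unconstrained(draws)
    if X.shape[0] > max_draws:
        idx = np.linspace(0, X.shape[0] - 1, max_draws).astype(int)
        X = X[idx]
    args = draws.problem.kernel_args()

    def logq(pts):
        return _kernels.logq_batch(np.ascontiguousarray(pts), *args)

    return bridge_log_marginal_likelihood(X, logq, seed=seed)


def random_baseline_evidence(trial_log: pd.DataFrame) -> float:
    """Exact log marginal likelihood of the parameter-free random model."""
    learn = trial_log[trial_log["phase"] == "learning"]
    n = int((learn["response"] >= 0).sum())
    return n * LOG_HALF


@dataclass
class ModelEvidence:
    model: str
    n_params: int
    log_marginal_likelihood: float
    mc_error: float
    log_posterior_model_prob: float = math.nan
    posterior_model_prob: float = math.nan
    log10_bf_vs_next: float | None = None
    rank: int = 0


def posterior_model_probabilities(log_evidences, prior_probs=None) -> np.ndarray:
    """p(M_i | D) from log marginal likelihoods, equal priors by default."""
    lz = np.asarray(log_evidences, dtype=float)
    if lz.size < 1:
        raise ValueError("need at least one model")
    if prior_probs is None:
        lp = np.zeros(lz.size)
    else:
        lp = np.log(np.asarray(prior_probs, dtype=float))
    w = lz + lp
    w -= w.max()
    p = np.exp(w)
    return p / p.sum()


def log10_bayes_factor(log_z_a: float, log_z_b: float) -> float:
    """log10 BF from two natural-log marginal likelihoods."""
    return (log_z_a - log_z_b) / math.log(10.0)


def rank_models(evidences: list[ModelEvidence]) -> list[ModelEvidence]:
    """Sort by evidence (ties to the more parsimonious model), attach
    posterior probabilities and pairwise log10 Bayes factors vs next rank."""
    ordered = sorted(evidences,
                     key=lambda e: (-e.log_marginal_likelihood, e.n_params))
    lz = np.array([e.log_marginal_likelihood for e in ordered])
    probs = posterior_model_probabilities(lz)
    lse = float(logsumexp(lz))
    for i, e in enumerate(ordered):
        e.rank = i + 1
        e.posterior_model_prob = float(probs[i])
        e.log_posterior_model_prob = float(e.log_marginal_likelihood - lse)
        if i + 1 < len(ordered):
            e.log10_bf_vs_next = log10_bayes_factor(
                e.log_marginal_likelihood, ordered[i + 1].log_marginal_likelihood)
        else:
            e.log10_bf_vs_next = None
    return ordered


def evidence_table(evidences: list[ModelEvidence]) -> pd.DataFrame:
    ranked = rank_models(evidences)
    return pd.DataFrame(
        [{"model": e.model, "n_params": e.n_params,
          "log_marginal_likelihood": e.log_marginal_likelihood,
          "mc_error": e.mc_error,
          "posterior_model_prob": e.posterior_model_prob,
          "log10_bf_vs_next": e.log10_bf_vs_next,
          "rank": e.rank}
         for e in ranked])


def compare_models(trial_log: pd.DataFrame, specs=None,
                   priors: PriorSpec | None = None,
                   n_chains: int = 4, n_iterations: int = 2000,
                   seed: int = 0, require_convergence: bool = False
                   ) -> pd.DataFrame:
    """Fit every model variant to the same trial log and rank by evidence.

    The random baseline's evidence is exact (no sampling); the others are
    fitted by MCMC and bridge-sampled.  ``require_convergence=True`` turns
    a failed R-hat gate into an error instead of a warning.
    """
    specs = [get_spec(s) if isinstance(s, str) else s
             for s in (specs or model_registry())]
    if not specs:
        raise ValueError("empty model list")
    evidences = []
    root = np.random.SeedSequence(seed)
    for spec, sub in zip(specs, root.spawn(len(specs))):
        s1, s2 = sub.generate_state(2) % (2**31 - 1)
        if spec.is_random_baseline:
            lz = random_baseline_evidence(trial_log)
            evidences.append(ModelEvidence(spec.name, 0, lz, 0.0))
            continue
        problem = build_hierarchical_model(spec, trial_log, priors)
        draws = sample_posterior(problem, n_chains, n_iterations, seed=int(s1),
                                 effort="fast")
        lz, err = evidence_from_fit(draws, seed=int(s2),
                                    require_convergence=require_convergence)
        evidences.append(ModelEvidence(spec.name, spec.n_params, lz, err))
    return evidence_table(evidences)
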