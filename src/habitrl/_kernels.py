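"""Numba-compiled numerical kernels.

Everything latency-critical lives here: the per-subject trial-loop
likelihoods (single-system softmax models and the two-system model), the
adaptive single-site Metropolis-within-Gibbs sweep used for hierarchical
posterior sampling, and a batch evaluator of the unnormalised log posterior
on unconstrained coordinates (consumed by bridge sampling).

Parameter kinds index the prior/bound families:
    0  alpha-type: support [0, 1], group-mean prior Beta(a, b)
    1  beta-type:  support [0, inf), group-mean prior Gamma(shape, scale)
    2  tau-type:   unbounded, group-mean prior Normal(mean, sd)

The hierarchical layout of a flattened state vector is
    mu[g, j] for g in groups, j in params   (G * P entries)
    log-or-raw sigma[j]                     (P entries)
    theta[s, j] for s in subjects           (S * P entries)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_ALPHA = 0
KIND_BETA = 1
KIND_TAU = 2

# roles inside the 5-slot single-system parameter vector
ROLE_ALPHA, ROLE_AREW, ROLE_AEXT, ROLE_BETA, ROLE_TAU = 0, 1, 2, 3, 4

_NEG_INF = -1.0e300


@njit(cache=False)
def _norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


@njit(cache=False)
def _kind_bounds(kind):
    if kind == KIND_ALPHA:
        return 0.0, 1.0
    if kind == KIND_BETA:
        return 0.0, np.inf
    return -np.inf, np.inf


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=False)
def _trunc_logpdf(x, mu, sig, kind):
    """Truncated-normal log density including the normalising constant."""
    z = (x - mu) / sig
    lp = -0.5 * z * z - math.log(sig) - _LOG_SQRT_2PI
    if kind == KIND_TAU:
        return lp
    if kind == KIND_ALPHA:
        denom = _norm_cdf((1.0 - mu) / sig) - _norm_cdf((0.0 - mu) / sig)
    else:  # beta-type: lower bound 0
        denom = 1.0 - _norm_cdf((0.0 - mu) / sig)
    if denom <= 0.0:
        return _NEG_INF
    return lp - math.log(denom)


@njit(cache=False)
def _mean_prior_logpdf(x, kind, a, b):
    """Normalised log prior of a group mean: Beta/Gamma/Normal by kind."""
    if kind == KIND_ALPHA:
        if x <= 0.0 or x >= 1.0:
            return _NEG_INF
        return ((a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x)
                + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b))
    if kind == KIND_BETA:
        if x <= 0.0:
            return _NEG_INF
        return ((a - 1.0) * math.log(x) - x / b
                - math.lgamma(a) - a * math.log(b))
    z = (x - a) / b
    return -0.5 * z * z - math.log(b) - _LOG_SQRT_2PI


@njit(cache=False)
def _halfnormal_logpdf(x, sc):
    return (-0.5 * x * x / (sc * sc)
            + math.log(2.0) - math.log(sc) - _LOG_SQRT_2PI)


@njit(cache=False)
def ll_single(p5, frac, stim, choice, reward, n):
    """Single-system log likelihood for one subject's learning phase.

    ``p5`` = (alpha, alpha_rew, alpha_ext, beta, tau); absent parameters are
    passed as 0.  ``choice`` uses -1 for miss trials.
    """
    V = np.zeros((6, 2))
    c0 = 0.0
    c1 = 0.0
    total = 0.0
    for t in range(n):
        ch = choice[t]
        if ch < 0:
            c0 = 0.0
            c1 = 0.0
            continue
        s = stim[t]
        d0 = p5[ROLE_BETA] * V[s, 0] + p5[ROLE_TAU] * c0
        d1 = p5[ROLE_BETA] * V[s, 1] + p5[ROLE_TAU] * c1
        # log softmax of the chosen option via the stable 2-option logistic
        gap = (d0 - d1) if ch == 0 else (d1 - d0)
        if gap > 0.0:
            total += -math.log1p(math.exp(-gap))
        else:
            total += gap - math.log1p(math.exp(gap))
        r = reward[t]
        if frac:
            rate = p5[ROLE_AREW] if r == 1 else p5[ROLE_AEXT]
        else:
            rate = p5[ROLE_ALPHA]
        V[s, ch] += rate * (r - V[s, ch])
        c0 = 1.0 if ch == 0 else 0.0
        c1 = 1.0 - c0
    return total


@njit(cache=False)
def ll_two_system(alpha, wg, wh, tau, hlat,
                  stim1, choice1, reward1, n1,
                  stim2, go2, dev2, n2, corr):
    """Two-system joint log likelihood over both phases for one subject."""
    Q = np.zeros((6, 2))
    H = np.zeros((6, 2))
    c0 = 0.0
    c1 = 0.0
    total = 0.0
    for t in range(n1):
        ch = choice1[t]
        if ch < 0:
            c0 = 0.0
            c1 = 0.0
            continue
        s = stim1[t]
        d0 = wg * Q[s, 0] + wh * H[s, 0] + tau * c0
        d1 = wg * Q[s, 1] + wh * H[s, 1] + tau * c1
        gap = (d0 - d1) if ch == 0 else (d1 - d0)
        if gap > 0.0:
            total += -math.log1p(math.exp(-gap))
        else:
            total += gap - math.log1p(math.exp(gap))
        r = reward1[t]
        Q[s, ch] += alpha * (r - Q[s, ch])
        H[s, ch] += alpha * (1.0 - H[s, ch])
        c0 = 1.0 if ch == 0 else 0.0
        c1 = 1.0 - c0
    # devaluation phase: go/no-go, no stickiness carried across the break
    cgo = 0.0
    cng = 0.0
    for t in range(n2):
        g = go2[t]
        if g < 0:
            cgo = 0.0
            cng = 0.0
            continue
        s = stim2[t]
        a = corr[s]
        u = 0.0 if dev2[t] == 1 else 1.0
        drive = wg * Q[s, a] * u + wh * H[s, a] + tau * (cgo - cng)
        # log P(go) = -log1p(exp(-drive)); log P(nogo) = -drive - log1p(exp(-drive))
        if drive > 0.0:
            lse = drive + math.log1p(math.exp(-drive))
        else:
            lse = math.log1p(math.exp(drive))
        if g == 1:
            total += drive - lse
            if hlat:
                H[s, a] += alpha * (1.0 - H[s, a])
            cgo = 1.0
            cng = 0.0
        else:
            total += -lse
            cgo = 0.0
            cng = 1.0
    return total


@njit(cache=False)
def _subject_ll(model_kind, th, roles, frac, hlat,
                stim1, choice1, reward1, n1,
                stim2, go2, dev2, n2, corr):
    """Dispatch: map a subject's compact parameter row onto the likelihood."""
    if model_kind == 0:
        p5 = np.zeros(5)
        for j in range(th.shape[0]):
            p5[roles[j]] = th[j]
        return ll_single(p5, frac, stim1, choice1, reward1, n1)
    return ll_two_system(th[0], th[1], th[2], th[3], hlat,
                         stim1, choice1, reward1, n1,
                         stim2, go2, dev2, n2, corr)


@njit(cache=False)
def _to_unc(x, kind):
    if kind == KIND_ALPHA:
        return math.log(x / (1.0 - x))
    if kind == KIND_BETA:
        return math.log(x)
    return x


@njit(cache=False)
def _from_unc(y, kind):
    if kind == KIND_ALPHA:
        return 1.0 / (1.0 + math.exp(-y))
    if kind == KIND_BETA:
        return math.exp(y)
    return y


@njit(cache=False)
def _log_jac(x, kind):
    """log |dx/dy| of the constraining transform, evaluated at x."""
    if kind == KIND_ALPHA:
        return math.log(x) + math.log(1.0 - x)
    if kind == KIND_BETA:
        return math.log(x)
    return 0.0


@njit(cache=False)
def _trans_logf(d, g, j, kind, mu, sigma, theta, group,
                model_kind, roles, frac, hlat,
                stim1, choice1, reward1, n1, stim2, go2, dev2, n2, corr,
                pa, pb, thp, ll_out):
    """Log target along the group-translation direction: mu[g, j] and all of
    group g's subjects shifted together by d (z-scores unchanged)."""
    xp = mu[g, j] + d
    if kind == KIND_ALPHA and (xp <= 0.0 or xp >= 1.0):
        return -1.0e308
    if kind == KIND_BETA and xp <= 0.0:
        return -1.0e308
    lo, hi = _kind_bounds(kind)
    f = _mean_prior_logpdf(xp, kind, pa, pb)
    S = theta.shape[0]
    P = theta.shape[1]
    for s in range(S):
        if group[s] != g:
            continue
        t = theta[s, j] + d
        if kind != KIND_TAU and (t <= lo or t >= hi):
            return -1.0e308
        for jj in range(P):
            thp[jj] = theta[s, jj]
        thp[j] = t
        ll = _subject_ll(model_kind, thp, roles, frac, hlat,
                         stim1[s], choice1[s], reward1[s], n1[s],
                         stim2[s], go2[s], dev2[s], n2[s], corr)
        ll_out[s] = ll
        f += ll + _trunc_logpdf(t, xp, sigma[j], kind)
    return f


@njit(cache=False)
def _scale_logf(eps, j, kind, sigma, mu, theta, group,
                model_kind, roles, frac, hlat,
                stim1, choice1, reward1, n1, stim2, go2, dev2, n2, corr,
                sd_scale_j, thp, ll_out):
    """Log target along the SD scale direction: sigma_j and all deviations
    of column j rescaled by exp(eps), with the (S+1)*eps Jacobian."""
    c = math.exp(eps)
    xp = c * sigma[j]
    lo, hi = _kind_bounds(kind)
    S = theta.shape[0]
    P = theta.shape[1]
    f = _halfnormal_logpdf(xp, sd_scale_j) + (S + 1) * eps
    for s in range(S):
        m = mu[group[s], j]
        t = m + c * (theta[s, j] - m)
        if kind != KIND_TAU and (t <= lo or t >= hi):
            return -1.0e308
        for jj in range(P):
            thp[jj] = theta[s, jj]
        thp[j] = t
        ll = _subject_ll(model_kind, thp, roles, frac, hlat,
                         stim1[s], choice1[s], reward1[s], n1[s],
                         stim2[s], go2[s], dev2[s], n2[s], corr)
        ll_out[s] = ll
        f += ll + _trunc_logpdf(t, m, xp, kind)
    return f


@njit(cache=False)
def run_chain(seed, n_iter, n_warmup,
              model_kind, roles, frac, hlat,
              kinds, prior_a, prior_b, sd_scale,
              group, stim1, choice1, reward1, n1,
              stim2, go2, dev2, n2, corr,
              mu0, sigma0, theta0, heavy):
    """One MCMC chain of adaptive Metropolis-within-Gibbs.

    Per iteration: (1) single-site subject updates on unconstrained scales;
    (2) a joint per-subject proposal from an adaptively estimated parameter
    covariance (handles the alpha-beta likelihood ridge); (3) group-mean and
    SD updates; (4) group translation moves (mu and its subjects shifted
    together) and SD scale moves (sigma and all deviations rescaled
    together), which decouple the hyperparameters from the subject block.
    Step sizes adapt in batches of 50 during warmup and are frozen after.
    Returns post-warmup draws, (n_iter - n_warmup, D), in the flattened
    layout documented at module level.
    """
    np.random.seed(seed)
    G = mu0.shape[0]
    P = mu0.shape[1]
    S = theta0.shape[0]
    mu = mu0.copy()
    sigma = sigma0.copy()
    theta = theta0.copy()

    # cached per-subject likelihoods
    ll_cur = np.empty(S)
    for s in range(S):
        ll_cur[s] = _subject_ll(model_kind, theta[s], roles, frac, hlat,
                                stim1[s], choice1[s], reward1[s], n1[s],
                                stim2[s], go2[s], dev2[s], n2[s], corr)

    ls_theta = np.full((S, P), math.log(0.25))
    ls_mu = np.full((G, P), math.log(0.1))
    ls_sig = np.full(P, math.log(0.2))
    ls_joint = np.zeros(S)
    acc_theta = np.zeros((S, P))
    acc_mu = np.zeros((G, P))
    acc_sig = np.zeros(P)
    acc_joint = np.zeros(S)

    # running moments of unconstrained subject vectors for joint proposals
    cov_n = 0
    cov_mean = np.zeros((S, P))
    cov_m2 = np.zeros((S, P, P))
    chol = np.zeros((S, P, P))
    chol_ready = False

    D = G * P + P + S * P
    kept = n_iter - n_warmup
    out = np.empty((kept, D))

    batch = 50
    n_batch = 0
    # hyper-block repetition schedule; the heavy profile buys the mixing
    # needed for large-S funnels, the light one suffices for small cohorts
    reps_col = np.empty(P)
    for j in range(P):
        if kinds[j] == KIND_ALPHA:
            reps_col[j] = 5.0 if heavy == 1 else 2.0
        elif kinds[j] == KIND_BETA:
            reps_col[j] = 3.0 if heavy == 1 else 1.0
        else:
            reps_col[j] = 2.0 if heavy == 1 else 1.0
    n_slice = 2 if heavy == 1 else 1
    n_indep = 3 if heavy == 1 else 1
    n_full = 8 if heavy == 1 else 2
    n_tele = 3 if heavy == 1 else 0
    yvec = np.empty(P)
    ypro = np.empty(P)
    thp = np.empty(P)
    zbuf = np.empty(P)
    ll_tmp = np.empty(S)
    ll_new_buf = np.empty(S)
    for it in range(n_iter):
        # --- (1) single-site subject updates, unconstrained scale ---
        for s in range(S):
            g = group[s]
            for j in range(P):
                kind = kinds[j]
                x = theta[s, j]
                y = _to_unc(x, kind)
                yp = y + math.exp(ls_theta[s, j]) * np.random.normal()
                xp = _from_unc(yp, kind)
                lo, hi = _kind_bounds(kinds[j])
                if not np.isfinite(xp) or xp <= lo or xp >= hi:
                    if kind == KIND_TAU and np.isfinite(xp):
                        pass  # tau is unbounded
                    else:
                        continue
                for jj in range(P):
                    thp[jj] = theta[s, jj]
                thp[j] = xp
                llp = _subject_ll(model_kind, thp, roles, frac, hlat,
                                  stim1[s], choice1[s], reward1[s], n1[s],
                                  stim2[s], go2[s], dev2[s], n2[s], corr)
                z0 = (x - mu[g, j]) / sigma[j]
                z1 = (xp - mu[g, j]) / sigma[j]
                la = (llp - ll_cur[s]) + 0.5 * (z0 * z0 - z1 * z1)
                la += _log_jac(xp, kind) - _log_jac(x, kind)
                if la >= 0.0 or np.random.random() < math.exp(la):
                    theta[s, j] = xp
                    ll_cur[s] = llp
                    acc_theta[s, j] += 1.0

        # --- (1b) prior-conditional independence proposals ---
        # candidate from TruncNormal(mu_g, sigma_j); proposal and prior terms
        # cancel, so acceptance is the bare likelihood ratio.  Very effective
        # for subjects whose data barely constrain a parameter.
        for s in range(S):
            g = group[s]
            for j in range(P):
                kind = kinds[j]
                lo, hi = _kind_bounds(kind)
                # several refreshes per column: flat or one-sided subject
                # likelihoods make this the dominant mixing move
                for _prop in range(n_indep):
                    xp = np.nan
                    for _try in range(100):
                        cand = mu[g, j] + sigma[j] * np.random.normal()
                        if kind == KIND_TAU or (lo < cand < hi):
                            xp = cand
                            break
                    if not np.isfinite(xp):
                        continue
                    for jj in range(P):
                        thp[jj] = theta[s, jj]
                    thp[j] = xp
                    llp = _subject_ll(model_kind, thp, roles, frac, hlat,
                                      stim1[s], choice1[s], reward1[s], n1[s],
                                      stim2[s], go2[s], dev2[s], n2[s], corr)
                    la = llp - ll_cur[s]
                    if la >= 0.0 or np.random.random() < math.exp(la):
                        theta[s, j] = xp
                        ll_cur[s] = llp

        # --- (1c) full-vector independence refreshes ---
        # resample a subject's whole parameter vector from the group
        # conditional (acceptance = likelihood ratio): the only move that
        # can hop between modes of a multimodal subject posterior, e.g. a
        # near-random subject fit as either low-beta or low-alpha/high-beta
        for s in range(S):
            g = group[s]
            for _prop in range(n_full):
                ok = True
                for j in range(P):
                    kind = kinds[j]
                    lo, hi = _kind_bounds(kind)
                    t = np.nan
                    for _try in range(100):
                        cand = mu[g, j] + sigma[j] * np.random.normal()
                        if kind == KIND_TAU or (lo < cand < hi):
                            t = cand
                            break
                    if not np.isfinite(t):
                        ok = False
                        break
                    thp[j] = t
                if not ok:
                    continue
                llp = _subject_ll(model_kind, thp, roles, frac, hlat,
                                  stim1[s], choice1[s], reward1[s], n1[s],
                                  stim2[s], go2[s], dev2[s], n2[s], corr)
                la = llp - ll_cur[s]
                if la >= 0.0 or np.random.random() < math.exp(la):
                    for j in range(P):
                        theta[s, j] = thp[j]
                    ll_cur[s] = llp

        # --- (2) joint covariance-informed subject updates ---
        if chol_ready:
            for s in range(S):
                g = group[s]
                for j in range(P):
                    yvec[j] = _to_unc(theta[s, j], kinds[j])
                sc = math.exp(ls_joint[s])
                for j in range(P):
                    zbuf[j] = np.random.normal()
                for j in range(P):
                    step = 0.0
                    for jj in range(j + 1):
                        step += chol[s, j, jj] * zbuf[jj]
                    ypro[j] = yvec[j] + sc * step
                ok = True
                for j in range(P):
                    kind = kinds[j]
                    xp = _from_unc(ypro[j], kind)
                    lo, hi = _kind_bounds(kind)
                    if not np.isfinite(xp) or (kind != KIND_TAU and (xp <= lo or xp >= hi)):
                        ok = False
                        break
                    thp[j] = xp
                if not ok:
                    continue
                llp = _subject_ll(model_kind, thp, roles, frac, hlat,
                                  stim1[s], choice1[s], reward1[s], n1[s],
                                  stim2[s], go2[s], dev2[s], n2[s], corr)
                la = llp - ll_cur[s]
                for j in range(P):
                    z0 = (theta[s, j] - mu[g, j]) / sigma[j]
                    z1 = (thp[j] - mu[g, j]) / sigma[j]
                    la += 0.5 * (z0 * z0 - z1 * z1)
                    la += _log_jac(thp[j], kinds[j]) - _log_jac(theta[s, j], kinds[j])
                if la >= 0.0 or np.random.random() < math.exp(la):
                    for j in range(P):
                        theta[s, j] = thp[j]
                    ll_cur[s] = llp
                    acc_joint[s] += 1.0

        # hyper-block interweaving: repeat the mu/sigma updates and the
        # translation/scale moves to decorrelate hyperparameters from the
        # subject block (dominant residual autocorrelation otherwise).
        # Learning-rate columns mix slowest (flat subject likelihoods and a
        # hyperparameter funnel when the subject SD is small), so they get
        # the most repetitions; sensitivity-type columns sit in between.
        max_rep = 5 if heavy == 1 else 2
        for _rep in range(max_rep):
            # --- (3a) group means ---
            for g in range(G):
                for j in range(P):
                    kind = kinds[j]
                    if _rep >= reps_col[j]:
                        continue
                    x = mu[g, j]
                    step = math.exp(ls_mu[g, j]) * np.random.normal()
                    if kind == KIND_BETA:
                        xp = x * math.exp(step)
                        jac = math.log(xp) - math.log(x)
                    else:
                        xp = x + step
                        jac = 0.0
                    if kind == KIND_ALPHA and (xp <= 0.0 or xp >= 1.0):
                        continue
                    la = (_mean_prior_logpdf(xp, kind, prior_a[j], prior_b[j])
                          - _mean_prior_logpdf(x, kind, prior_a[j], prior_b[j]) + jac)
                    for s in range(S):
                        if group[s] == g:
                            la += (_trunc_logpdf(theta[s, j], xp, sigma[j], kind)
                                   - _trunc_logpdf(theta[s, j], x, sigma[j], kind))
                    if la >= 0.0 or np.random.random() < math.exp(la):
                        mu[g, j] = xp
                        acc_mu[g, j] += 1.0

            # --- shared subject SDs (log-scale walk, half-normal prior) ---
            for j in range(P):
                kind = kinds[j]
                if _rep >= reps_col[j]:
                    continue
                x = sigma[j]
                xp = x * math.exp(math.exp(ls_sig[j]) * np.random.normal())
                sc = sd_scale[j]
                la = (-0.5 * (xp * xp - x * x) / (sc * sc)
                      + math.log(xp) - math.log(x))
                for s in range(S):
                    la += (_trunc_logpdf(theta[s, j], mu[group[s], j], xp, kind)
                           - _trunc_logpdf(theta[s, j], mu[group[s], j], x, kind))
                if la >= 0.0 or np.random.random() < math.exp(la):
                    sigma[j] = xp
                    acc_sig[j] += 1.0

        # --- (4) group translation direction: slice sampling ---
        # mu[g, j] and its subjects move together (non-centered mu update);
        # slice sampling self-tunes the step along this direction
        for g in range(G):
            for j in range(P):
                kind = kinds[j]
                wt = 0.8 if kind == KIND_BETA else 0.3
                f0 = _trans_logf(0.0, g, j, kind, mu, sigma, theta, group,
                                 model_kind, roles, frac, hlat,
                                 stim1, choice1, reward1, n1,
                                 stim2, go2, dev2, n2, corr,
                                 prior_a[j], prior_b[j], thp, ll_tmp)
                yslice = f0 + math.log(np.random.random())
                L = -wt * np.random.random()
                R = L + wt
                for _ in range(4):
                    if _trans_logf(L, g, j, kind, mu, sigma, theta, group,
                                   model_kind, roles, frac, hlat,
                                   stim1, choice1, reward1, n1,
                                   stim2, go2, dev2, n2, corr,
                                   prior_a[j], prior_b[j], thp, ll_tmp) > yslice:
                        L -= wt
                    else:
                        break
                for _ in range(4):
                    if _trans_logf(R, g, j, kind, mu, sigma, theta, group,
                                   model_kind, roles, frac, hlat,
                                   stim1, choice1, reward1, n1,
                                   stim2, go2, dev2, n2, corr,
                                   prior_a[j], prior_b[j], thp, ll_tmp) > yslice:
                        R += wt
                    else:
                        break
                for _ in range(30):
                    d = L + (R - L) * np.random.random()
                    fd = _trans_logf(d, g, j, kind, mu, sigma, theta, group,
                                     model_kind, roles, frac, hlat,
                                     stim1, choice1, reward1, n1,
                                     stim2, go2, dev2, n2, corr,
                                     prior_a[j], prior_b[j], thp, ll_new_buf)
                    if fd > yslice:
                        mu[g, j] += d
                        for ss in range(S):
                            if group[ss] == g:
                                theta[ss, j] += d
                                ll_cur[ss] = ll_new_buf[ss]
                        break
                    if d < 0.0:
                        L = d
                    else:
                        R = d

        # --- (5) SD scale direction: slice sampling ---
        # sigma_j moves jointly with all its deviations (non-centered
        # interweave); slice sampling is self-tuning along this direction,
        # which random-walk steps traverse too slowly.  Two passes per sweep.
        for _srep in range(n_slice):
          for j in range(P):
            kind = kinds[j]
            if kind == KIND_TAU and _srep > 0:
                continue
            f0 = _scale_logf(0.0, j, kind, sigma, mu, theta, group,
                             model_kind, roles, frac, hlat,
                             stim1, choice1, reward1, n1,
                             stim2, go2, dev2, n2, corr,
                             sd_scale[j], thp, ll_tmp)
            yslice = f0 + math.log(np.random.random())
            w = 0.5
            L = -w * np.random.random()
            R = L + w
            for _ in range(6):
                if _scale_logf(L, j, kind, sigma, mu, theta, group,
                               model_kind, roles, frac, hlat,
                               stim1, choice1, reward1, n1,
                               stim2, go2, dev2, n2, corr,
                               sd_scale[j], thp, ll_tmp) > yslice:
                    L -= w
                else:
                    break
            for _ in range(6):
                if _scale_logf(R, j, kind, sigma, mu, theta, group,
                               model_kind, roles, frac, hlat,
                               stim1, choice1, reward1, n1,
                               stim2, go2, dev2, n2, corr,
                               sd_scale[j], thp, ll_tmp) > yslice:
                    R += w
                else:
                    break
            for _ in range(30):
                e = L + (R - L) * np.random.random()
                fe = _scale_logf(e, j, kind, sigma, mu, theta, group,
                                 model_kind, roles, frac, hlat,
                                 stim1, choice1, reward1, n1,
                                 stim2, go2, dev2, n2, corr,
                                 sd_scale[j], thp, ll_new_buf)
                if fe > yslice:
                    c = math.exp(e)
                    sigma[j] = c * sigma[j]
                    for ss in range(S):
                        m = mu[group[ss], j]
                        theta[ss, j] = m + c * (theta[ss, j] - m)
                        ll_cur[ss] = ll_new_buf[ss]
                    break
                if e < 0.0:
                    L = e
                else:
                    R = e

        # --- (5b) sigma teleport: propose a new SD and refresh every
        # subject deviation from the new conditional; the truncated-normal
        # prior and proposal terms cancel, leaving the likelihood ratio.
        # Jumps the SD across its range in one move.
        for j in range(P):
            kind = kinds[j]
            if kind != KIND_ALPHA:
                continue
            lo, hi = _kind_bounds(kind)
            for _tele in range(n_tele):
                x = sigma[j]
                xp = x * math.exp(0.6 * np.random.normal())
                la = (_halfnormal_logpdf(xp, sd_scale[j])
                      - _halfnormal_logpdf(x, sd_scale[j])
                      + math.log(xp) - math.log(x))  # log-RW Jacobian
                ok = True
                for ss in range(S):
                    m = mu[group[ss], j]
                    t = np.nan
                    for _try in range(100):
                        cand = m + xp * np.random.normal()
                        if kind == KIND_TAU or (lo < cand < hi):
                            t = cand
                            break
                    if not np.isfinite(t):
                        ok = False
                        break
                    for jj in range(P):
                        thp[jj] = theta[ss, jj]
                    thp[j] = t
                    ll_new_buf[ss] = _subject_ll(model_kind, thp, roles, frac, hlat,
                                                 stim1[ss], choice1[ss], reward1[ss],
                                                 n1[ss], stim2[ss], go2[ss], dev2[ss],
                                                 n2[ss], corr)
                    ll_tmp[ss] = t
                    la += ll_new_buf[ss] - ll_cur[ss]
                if not ok:
                    continue
                if la >= 0.0 or np.random.random() < math.exp(la):
                    sigma[j] = xp
                    for ss in range(S):
                        theta[ss, j] = ll_tmp[ss]
                        ll_cur[ss] = ll_new_buf[ss]

        # --- accumulate unconstrained subject moments for joint proposals ---
        if it >= 100 and it < n_warmup:
            cov_n += 1
            for s in range(S):
                for j in range(P):
                    yvec[j] = _to_unc(theta[s, j], kinds[j])
                for j in range(P):
                    d1 = yvec[j] - cov_mean[s, j]
                    cov_mean[s, j] += d1 / cov_n
                    for jj in range(P):
                        cov_m2[s, j, jj] += d1 * (yvec[jj] - cov_mean[s, jj])

        # --- warmup step-size adaptation ---
        if it < n_warmup and (it + 1) % batch == 0:
            n_batch += 1
            delta = min(0.25, 1.0 / math.sqrt(n_batch))
            for s in range(S):
                for j in range(P):
                    ls_theta[s, j] += delta if acc_theta[s, j] / batch > 0.44 else -delta
                    acc_theta[s, j] = 0.0
                ls_joint[s] += delta if acc_joint[s] / batch > 0.3 else -delta
                acc_joint[s] = 0.0
            for g in range(G):
                for j in range(P):
                    ls_mu[g, j] += delta if acc_mu[g, j] / (reps_col[j] * batch) > 0.44 else -delta
                    acc_mu[g, j] = 0.0
            for j in range(P):
                ls_sig[j] += delta if acc_sig[j] / (reps_col[j] * batch) > 0.44 else -delta
                acc_sig[j] = 0.0
            # refresh per-subject proposal choleskys from accumulated moments
            if cov_n >= 10 * P:
                fac = 2.38 / math.sqrt(P)
                for s in range(S):
                    C = cov_m2[s] / (cov_n - 1)
                    for j in range(P):
                        C[j, j] += 1e-6
                    chol[s] = np.linalg.cholesky(C) * fac
                chol_ready = True

        if it >= n_warmup:
            k = it - n_warmup
            idx = 0
            for g in range(G):
                for j in range(P):
                    out[k, idx] = mu[g, j]
                    idx += 1
            for j in range(P):
                out[k, idx] = sigma[j]
                idx += 1
            for s in range(S):
                for j in range(P):
                    out[k, idx] = theta[s, j]
                    idx += 1
    return out


@njit(cache=False)
def logq_batch(X, model_kind, roles, frac, hlat,
               kinds, prior_a, prior_b, sd_scale,
               group, stim1, choice1, reward1, n1,
               stim2, go2, dev2, n2, corr):
    """Unnormalised log posterior (with Jacobian) on unconstrained coordinates.

    Transforms per dimension: logit for alpha-type, log for beta-type and for
    every SD, identity for tau-type.  All prior densities are fully
    normalised, so the bridge estimate of the normalising constant of this
    density is the model's absolute log marginal likelihood.
    """
    N = X.shape[0]
    G = np.max(group) + 1 if group.shape[0] > 0 else 2
    P = kinds.shape[0]
    S = group.shape[0]
    out = np.empty(N)
    for i in range(N):
        lp = 0.0
        idx = 0
        mu = np.empty((G, P))
        for g in range(G):
            for j in range(P):
                y = X[i, idx]
                idx += 1
                kind = kinds[j]
                if kind == KIND_ALPHA:
                    ey = 1.0 / (1.0 + math.exp(-y))
                    mu[g, j] = ey
                    lp += math.log(ey) + math.log(1.0 - ey)  # Jacobian
                elif kind == KIND_BETA:
                    mu[g, j] = math.exp(y)
                    lp += y
                else:
                    mu[g, j] = y
                lp += _mean_prior_logpdf(mu[g, j], kind, prior_a[j], prior_b[j])
        sigma = np.empty(P)
        for j in range(P):
            y = X[i, idx]
            idx += 1
            sigma[j] = math.exp(y)
            lp += _halfnormal_logpdf(sigma[j], sd_scale[j]) + y  # prior + Jacobian
        th = np.empty(P)
        for s in range(S):
            for j in range(P):
                y = X[i, idx]
                idx += 1
                kind = kinds[j]
                if kind == KIND_ALPHA:
                    ey = 1.0 / (1.0 + math.exp(-y))
                    th[j] = ey
                    lp += math.log(ey) + math.log(1.0 - ey)
                elif kind == KIND_BETA:
                    th[j] = math.exp(y)
                    lp += y
                else:
                    th[j] = y
                lp += _trunc_logpdf(th[j], mu[group[s], j], sigma[j], kind)
            if lp > _NEG_INF:
                lp += _subject_ll(model_kind, th, roles, frac, hlat,
                                  stim1[s], choice1[s], reward1[s], n1[s],
                                  stim2[s], go2[s], dev2[s], n2[s], corr)
        out[i] = lp
    return out
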