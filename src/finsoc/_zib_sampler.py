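"""Adaptive Metropolis-within-Gibbs sampler for the zero-inflated
binomial GLMM with multi-membership random intercepts.

Model per dyad d with members (i_d, j_d):

    y_d ~ pi * delta_0 + (1 - pi) * Binomial(n_d, p_d)
    logit(p_d) = x_d' beta + u_{i_d} + u_{j_d}
    u_k ~ Normal(0, sigma_u),  sigma_u ~ half-Cauchy(0, gamma)
    beta_0 ~ Normal(0, sd_intercept), slopes ~ Normal(0, sd_slope)
    logit(pi) ~ Normal(0, sd_intercept)

The random effects are sampled in the non-centred parameterisation
u_k = sigma_u * z_k with z_k ~ Normal(0, 1), which avoids the funnel
pathology: single-site steps on z keep an O(1) scale however small
sigma_u is, and sigma_u moves through the likelihood directly. One
iteration performs, in order:

* per-coordinate random-walk updates of each fixed effect, then a block
  move drawn from the running empirical covariance of the beta draws
  (Haario-style adaptive Metropolis) once enough warmup history exists;
* a single-site sweep over the z_k, each touching only that
  individual's dyads with the per-dyad log-likelihood cached;
* a likelihood-invariant "sweep" move trading the intercept against the
  random-effect mean (eta unchanged, only priors enter), which
  decorrelates beta_0 from mean(u);
* a random-walk update of log sigma_u (z fixed, so eta rescales);
* a random-walk update of logit pi.

Proposal scales adapt during warmup by Robbins-Monro toward standard
acceptance targets (0.25 for block moves, 0.44 for scalar moves).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TARGET_BLOCK = 0.25
TARGET_SITE = 0.44
# bounds on log(sigma_u); proposals outside are clamped, keeping sigma^2
# away from floating-point under/overflow
LOG_SIGMA_MIN = -12.0
LOG_SIGMA_MAX = 8.0


@njit(cache=True, inline="always")
def _softplus(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True, inline="always")
def _zib_ll(y, n, eta, log_pi, log1m_pi, lchoose):
    sp = _softplus(eta)
    if y == 0:
        a = log_pi
        b = log1m_pi - n * sp
        if a > b:
            return a + np.log1p(np.exp(b - a))
        return b + np.log1p(np.exp(a - b))
    return log1m_pi + lchoose + y * eta - n * sp


@njit(cache=True)
def _all_ll(y, n, eta, log_pi, log1m_pi, lchoose, out):
    for d in range(y.size):
        out[d] = _zib_ll(y[d], n[d], eta[d], log_pi, log1m_pi, lchoose[d])


@njit(cache=True, inline="always")
def _half_cauchy_logpdf(s, scale):
    return -np.log1p((s / scale) ** 2)


@njit(cache=True)
def run_chain(
    X,
    y,
    n,
    lchoose,
    dyad_i,
    dyad_j,
    ind_ptr,
    ind_dyads,
    n_ind,
    iterations,
    warmup,
    seed,
    sd_intercept,
    sd_slope,
    cauchy_scale,
):
    np.random.seed(seed)
    n_dyads, p = X.shape
    n_keep = iterations - warmup

    beta = np.zeros(p)
    z = np.empty(n_ind)
    for k in range(n_ind):
        z[k] = 0.1 * np.random.normal()
    log_sigma = np.log(0.5)
    sigma = np.exp(log_sigma)
    logit_pi = -2.0

    zsum = np.zeros(n_dyads)
    for d in range(n_dyads):
        zsum[d] = z[dyad_i[d]] + z[dyad_j[d]]
    eta = X @ beta + sigma * zsum
    log_pi = logit_pi - _softplus(logit_pi)
    log1m_pi = -_softplus(logit_pi)
    ll = np.empty(n_dyads)
    _all_ll(y, n, eta, log_pi, log1m_pi, lchoose, ll)

    prior_sd = np.empty(p)
    prior_sd[0] = sd_intercept
    for k in range(1, p):
        prior_sd[k] = sd_slope

    # adapted log step sizes
    ls_coord = np.full(p, np.log(0.1))
    ls_block = np.log(1.0)  # multiplies the 2.38/sqrt(p) covariance proposal
    ls_z = np.full(n_ind, np.log(0.5))
    ls_sigma = np.log(0.3)
    ls_pi = np.log(0.5)
    ls_sweep = np.log(0.2)

    # running moments of beta for the adaptive block proposal
    cov_start = warmup // 4
    cov_count = 0
    cov_mean = np.zeros(p)
    cov_scatter = np.zeros((p, p))

    beta_draws = np.empty((n_keep, p))
    u_draws = np.empty((n_keep, n_ind))
    sigma_draws = np.empty(n_keep)
    pi_draws = np.empty(n_keep)

    eta_prop = np.empty(n_dyads)
    ll_prop = np.empty(n_dyads)

    for it in range(iterations):
        adapt = it < warmup
        gamma = 1.0 / np.sqrt(1.0 + it) if adapt else 0.0

        # --- fixed effects: per-coordinate random walks -------------------
        for k in range(p):
            db = np.exp(ls_coord[k]) * np.random.normal()
            b_new = beta[k] + db
            for d in range(n_dyads):
                eta_prop[d] = eta[d] + X[d, k] * db
            _all_ll(y, n, eta_prop, log_pi, log1m_pi, lchoose, ll_prop)
            delta = -0.5 * (b_new * b_new - beta[k] * beta[k]) / (
                prior_sd[k] * prior_sd[k]
            )
            for d in range(n_dyads):
                delta += ll_prop[d] - ll[d]
            acc_prob = np.exp(min(0.0, delta))
            if np.random.random() < acc_prob:
                beta[k] = b_new
                for d in range(n_dyads):
                    eta[d] = eta_prop[d]
                    ll[d] = ll_prop[d]
            if adapt:
                ls_coord[k] += gamma * (acc_prob - TARGET_SITE)

        # --- fixed effects: adaptive-covariance block move ----------------
        if it >= cov_start:
            cov_count += 1
            for a in range(p):
                diff_a = beta[a] - cov_mean[a]
                cov_mean[a] += diff_a / cov_count
                for b in range(p):
                    cov_scatter[a, b] += diff_a * (beta[b] - cov_mean[b])
        if cov_count > 20 * p:
            cov = cov_scatter / (cov_count - 1)
            for a in range(p):
                cov[a, a] += 1e-12 + 1e-8 * cov[a, a]
            L = np.linalg.cholesky(cov)
            zvec = np.empty(p)
            for k in range(p):
                zvec[k] = np.random.normal()
            dbeta = (np.exp(ls_block) * 2.38 / np.sqrt(p)) * (L @ zvec)
            for d in range(n_dyads):
                acc = eta[d]
                for k in range(p):
                    acc += X[d, k] * dbeta[k]
                eta_prop[d] = acc
            _all_ll(y, n, eta_prop, log_pi, log1m_pi, lchoose, ll_prop)
            delta = 0.0
            for d in range(n_dyads):
                delta += ll_prop[d] - ll[d]
            for k in range(p):
                b_new = beta[k] + dbeta[k]
                delta += -0.5 * (b_new * b_new - beta[k] * beta[k]) / (
                    prior_sd[k] * prior_sd[k]
                )
            acc_prob = np.exp(min(0.0, delta))
            if np.random.random() < acc_prob:
                for k in range(p):
                    beta[k] += dbeta[k]
                for d in range(n_dyads):
                    eta[d] = eta_prop[d]
                    ll[d] = ll_prop[d]
            if adapt:
                ls_block += gamma * (acc_prob - TARGET_BLOCK)

        # --- single-site z sweeps (non-centred random effects) ------------
        for _rep in range(2):
            for k in range(n_ind):
                dz = np.exp(ls_z[k]) * np.random.normal()
                z_new = z[k] + dz
                delta = -0.5 * (z_new * z_new - z[k] * z[k])
                du = sigma * dz
                for t in range(ind_ptr[k], ind_ptr[k + 1]):
                    d = ind_dyads[t]
                    delta += (
                        _zib_ll(
                            y[d], n[d], eta[d] + du, log_pi, log1m_pi, lchoose[d]
                        )
                        - ll[d]
                    )
                acc_prob = np.exp(min(0.0, delta))
                if np.random.random() < acc_prob:
                    z[k] = z_new
                    for t in range(ind_ptr[k], ind_ptr[k + 1]):
                        d = ind_dyads[t]
                        eta[d] += du
                        zsum[d] += dz
                        ll[d] = _zib_ll(
                            y[d], n[d], eta[d], log_pi, log1m_pi, lchoose[d]
                        )
                if adapt:
                    ls_z[k] += gamma * (acc_prob - TARGET_SITE)

            # --- intercept/random-effect sweep move (eta invariant) -------
            # beta_0 -> beta_0 + 2*sigma*dlt, z_k -> z_k - dlt keeps every
            # eta_d fixed (each dyad carries two z's); only priors change.
            dlt = np.exp(ls_sweep) * np.random.normal()
            b0_new = beta[0] + 2.0 * sigma * dlt
            delta = -0.5 * (b0_new * b0_new - beta[0] * beta[0]) / (
                sd_intercept * sd_intercept
            )
            sz2_old = 0.0
            sz2_new = 0.0
            for k in range(n_ind):
                sz2_old += z[k] * z[k]
                sz2_new += (z[k] - dlt) * (z[k] - dlt)
            delta += -0.5 * (sz2_new - sz2_old)
            acc_prob = np.exp(min(0.0, delta))
            if np.random.random() < acc_prob:
                beta[0] = b0_new
                for k in range(n_ind):
                    z[k] -= dlt
                for d in range(n_dyads):
                    zsum[d] -= 2.0 * dlt
            if adapt:
                ls_sweep += gamma * (acc_prob - TARGET_SITE)

            # --- sigma_u update (z fixed; eta rescales through the data) --
            ls_new = log_sigma + np.exp(ls_sigma) * np.random.normal()
            if ls_new < LOG_SIGMA_MIN:
                ls_new = LOG_SIGMA_MIN
            elif ls_new > LOG_SIGMA_MAX:
                ls_new = LOG_SIGMA_MAX
            s_new = np.exp(ls_new)
            for d in range(n_dyads):
                eta_prop[d] = eta[d] + (s_new - sigma) * zsum[d]
            _all_ll(y, n, eta_prop, log_pi, log1m_pi, lchoose, ll_prop)
            # half-Cauchy prior on sigma plus the log-parameterisation Jacobian
            delta = (
                _half_cauchy_logpdf(s_new, cauchy_scale)
                - _half_cauchy_logpdf(sigma, cauchy_scale)
                + (ls_new - log_sigma)
            )
            for d in range(n_dyads):
                delta += ll_prop[d] - ll[d]
            acc_prob = np.exp(min(0.0, delta))
            if np.random.random() < acc_prob:
                log_sigma = ls_new
                sigma = s_new
                for d in range(n_dyads):
                    eta[d] = eta_prop[d]
                    ll[d] = ll_prop[d]
            if adapt:
                ls_sigma += gamma * (acc_prob - TARGET_SITE)

        # --- zero-inflation update ----------------------------------------
        lpi_new = logit_pi + np.exp(ls_pi) * np.random.normal()
        log_pi_new = lpi_new - _softplus(lpi_new)
        log1m_pi_new = -_softplus(lpi_new)
        _all_ll(y, n, eta, log_pi_new, log1m_pi_new, lchoose, ll_prop)
        delta = -0.5 * (lpi_new * lpi_new - logit_pi * logit_pi) / (
            sd_intercept * sd_intercept
        )
        for d in range(n_dyads):
            delta += ll_prop[d] - ll[d]
        acc_prob = np.exp(min(0.0, delta))
        if np.random.random() < acc_prob:
            logit_pi = lpi_new
            log_pi = log_pi_new
            log1m_pi = log1m_pi_new
            for d in range(n_dyads):
                ll[d] = ll_prop[d]
        if adapt:
            ls_pi += gamma * (acc_prob - TARGET_SITE)

        if it >= warmup:
            idx = it - warmup
            for k in range(p):
                beta_draws[idx, k] = beta[k]
            for k in range(n_ind):
                u_draws[idx, k] = sigma * z[k]
            sigma_draws[idx] = sigma
            pi_draws[idx] = 1.0 / (1.0 + np.exp(-logit_pi))

    return beta_draws, u_draws, sigma_draws, pi_draws


def build_individual_index(
    dyad_i: np.ndarray, dyad_j: np.ndarray, n_ind: int
) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style map individual -> indices of the dyads containing it."""
    counts = np.zeros(n_ind, dtype=np.int64)
    for arr in (dyad_i, dyad_j):
        np.add.at(counts, arr, 1)
    ptr = np.zeros(n_ind + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    dyads = np.empty(ptr[-1], dtype=np.int64)
    cursor = ptr[:-1].copy()
    for d in range(dyad_i.size):
        for k in (dyad_i[d], dyad_j[d]):
            dyads[cursor[k]] = d
            cursor[k] += 1
    return ptr, dyads
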