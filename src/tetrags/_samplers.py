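"""Numba Gibbs-sampling kernels for the Bayesian whole-genome regressions.

Single-site updates are inherently sequential, so the inner loops are
jitted.  All kernels work on a centered, C-contiguous (p, n) transposed
genotype matrix and return posterior means from post-burn-in thinned
samples plus a status flag (0 = ok; otherwise the 1-based iteration at
which the chain state became non-finite).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chi2(df: float) -> float:
    return 2.0 * np.random.gamma(df / 2.0, 1.0)


@njit(cache=True)
def _inv_gaussian(mu: float, lam: float) -> float:
    # Michael-Schucany-Haas transform
    v = np.random.normal() ** 2
    x = mu + mu * mu * v / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v
    )
    if x <= 0.0 or np.random.random() > mu / (mu + x):
        x = mu * mu / max(x, 1e-300)
    return x


@njit(cache=True)
def bayes_ab_kernel(
    Xt, y, n_iter, burn_in, thinning, nu0, S0, nue, Se, pi_incl, seed
):
    """Bayes A (pi_incl = 1) / Bayes B Gibbs sampler.

    Marker effects carry marker-specific variances with a scaled
    inverse-chi-square prior (df nu0, scale S0); Bayes B adds a
    point-mass-at-zero mixture with prior inclusion probability
    ``pi_incl``.
    """
    np.random.seed(seed)
    p, n = Xt.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s

    mu = y.mean()
    e = y - mu
    beta = np.zeros(p)
    sigma2_j = np.full(p, max(S0 / (nu0 + 2.0), 1e-12))
    vy = e @ e / n
    sigma2_e = max(vy * 0.5, 1e-12)

    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    s2e_sum = 0.0
    n_kept = 0

    for it in range(n_iter):
        # intercept
        m = mu + e.mean()
        mu_new = np.random.normal(m, np.sqrt(sigma2_e / n))
        e += mu - mu_new
        mu = mu_new
        for j in range(p):
            if xtx[j] <= 0.0:  # monomorphic after centering
                continue
            bj = beta[j]
            rhs = Xt[j] @ e + xtx[j] * bj
            if pi_incl < 1.0:
                q = sigma2_e + sigma2_j[j] * xtx[j]
                lbf = 0.5 * np.log(sigma2_e / q) + 0.5 * rhs * rhs * sigma2_j[j] / (
                    sigma2_e * q
                )
                odds = (1.0 - pi_incl) / pi_incl * np.exp(-lbf)
                incl = np.random.random() < 1.0 / (1.0 + odds)
            else:
                incl = True
            if incl:
                v = 1.0 / (xtx[j] / sigma2_e + 1.0 / sigma2_j[j])
                bnew = np.random.normal(v * rhs / sigma2_e, np.sqrt(v))
            else:
                bnew = 0.0
            if bnew != bj:
                d = bj - bnew
                for i in range(n):
                    e[i] += Xt[j, i] * d
                beta[j] = bnew
            if incl:
                sigma2_j[j] = max((S0 + bnew * bnew) / _chi2(nu0 + 1.0), 1e-12)
                incl_flag = 1.0
            else:
                sigma2_j[j] = max(S0 / _chi2(nu0), 1e-12)
                incl_flag = 0.0
            if it >= burn_in and (it - burn_in) % thinning == 0:
                incl_sum[j] += incl_flag
        sse = e @ e
        sigma2_e = max((sse + Se) / _chi2(n + nue), 1e-12)
        if not np.isfinite(sigma2_e):
            return beta_sum, mu_sum, s2e_sum, incl_sum, 0, it + 1
        if it >= burn_in and (it - burn_in) % thinning == 0:
            beta_sum += beta
            mu_sum += mu
            s2e_sum += sigma2_e
            n_kept += 1
    return beta_sum, mu_sum, s2e_sum, incl_sum, n_kept, 0


@njit(cache=True)
def bayesian_lasso_kernel(
    Xt, y, n_iter, burn_in, thinning, lambda2_init, gamma_shape, gamma_rate, nue, Se, seed
):
    """Bayesian Lasso Gibbs sampler (double-exponential prior on effects
    via the exponential scale mixture of normals; lambda^2 carries a
    gamma hyperprior)."""
    np.random.seed(seed)
    p, n = Xt.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s

    mu = y.mean()
    e = y - mu
    beta = np.zeros(p)
    inv_tau2 = np.full(p, lambda2_init)
    lambda2 = lambda2_init
    vy = e @ e / n
    sigma2_e = max(vy * 0.5, 1e-12)

    beta_sum = np.zeros(p)
    mu_sum = 0.0
    s2e_sum = 0.0
    lam2_sum = 0.0
    n_kept = 0

    for it in range(n_iter):
        m = mu + e.mean()
        mu_new = np.random.normal(m, np.sqrt(sigma2_e / n))
        e += mu - mu_new
        mu = mu_new
        sum_tau2 = 0.0
        sum_b2_invtau2 = 0.0
        for j in range(p):
            if xtx[j] <= 0.0:
                sum_tau2 += 1.0 / inv_tau2[j]
                continue
            bj = beta[j]
            rhs = Xt[j] @ e + xtx[j] * bj
            denom = xtx[j] + inv_tau2[j]
            bnew = np.random.normal(rhs / denom, np.sqrt(sigma2_e / denom))
            if bnew != bj:
                d = bj - bnew
                for i in range(n):
                    e[i] += Xt[j, i] * d
                beta[j] = bnew
            b2 = max(bnew * bnew, 1e-12)
            inv_tau2[j] = _inv_gaussian(np.sqrt(lambda2 * sigma2_e / b2), lambda2)
            sum_tau2 += 1.0 / inv_tau2[j]
            sum_b2_invtau2 += b2 * inv_tau2[j]
        lambda2 = np.random.gamma(p + gamma_shape, 1.0 / (sum_tau2 / 2.0 + gamma_rate))
        sse = e @ e
        sigma2_e = max((sse + sum_b2_invtau2 + Se) / _chi2(n + p + nue), 1e-12)
        if not np.isfinite(sigma2_e) or not np.isfinite(lambda2):
            return beta_sum, mu_sum, s2e_sum, lam2_sum, 0, it + 1
        if it >= burn_in and (it - burn_in) % thinning == 0:
            beta_sum += beta
            mu_sum += mu
            s2e_sum += sigma2_e
            lam2_sum += lambda2
            n_kept += 1
    return beta_sum, mu_sum, s2e_sum, lam2_sum, n_kept, 0
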