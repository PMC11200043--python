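"""Low-level numerical kernels (numba-compiled).

Two hot loops live here:

* an L1-penalized logistic-regression *path* solver (coordinate descent with
  an unpenalized intercept, warm starts along a decreasing λ grid, exact
  zeros via soft thresholding) — the workhorse of nodewise Ising estimation,
  called thousands of times inside permutation and bootstrap loops;
* a Gibbs sampler for the Ising model.

The path solver is a proximal-Newton scheme: an outer IRLS loop refreshes
the logistic weights and builds the weighted Gram matrix (cheap for binary
predictors via per-row nonzero lists), an inner coordinate-descent loop
solves the L1 quadratic subproblem entirely in coefficient space (soft
thresholding, hence exact zeros), and solutions are warm-started from the
previous λ. Weights are floored to keep the subproblem well-conditioned
under separation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["logistic_lasso_path", "gibbs_sample", "lambda_max"]


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ for which all penalized coefficients are exactly zero.

    With an unpenalized intercept at logit(mean(y)) the KKT condition gives
    λ_max = max_j |x_j'(y − ȳ)| / n.
    """
    n = y.shape[0]
    r = y - y.mean()
    return float(np.abs(X.T @ r).max() / n)


@njit(cache=True)
def logistic_lasso_path(X, y, lambdas, tol, max_iter):  # pragma: no cover - jit
    """Solve min_{b0,β} −ℓ(b0, β)/n + λ‖β‖₁ along a decreasing λ path.

    Parameters: X (n×m, C-contiguous float64), y in {0,1}, lambdas decreasing.
    Returns (intercepts[L], coefs[L,m], logliks[L], iters[L]) where loglik is
    the unpenalized Bernoulli log-likelihood at each solution and iters the
    number of outer Newton steps used. ``tol`` bounds the largest coefficient
    change over one Newton step; ``max_iter`` caps the outer (IRLS)
    iterations per λ (iters == max_iter signals non-convergence).
    """
    n, m = X.shape
    L = lambdas.shape[0]
    intercepts = np.empty(L)
    coefs = np.empty((L, m))
    logliks = np.empty(L)
    iters = np.zeros(L, dtype=np.int64)

    # per-row lists of nonzero predictors (X is binary in practice, so the
    # weighted Gram reduces to sums of weights over co-occurrence rows)
    row_ptr = np.empty(n + 1, dtype=np.int64)
    row_ptr[0] = 0
    for i in range(n):
        c = 0
        for j in range(m):
            if X[i, j] != 0.0:
                c += 1
        row_ptr[i + 1] = row_ptr[i] + c
    row_idx = np.empty(row_ptr[n], dtype=np.int64)
    row_val = np.empty(row_ptr[n])
    for i in range(n):
        k = row_ptr[i]
        for j in range(m):
            if X[i, j] != 0.0:
                row_idx[k] = j
                row_val[k] = X[i, j]
                k += 1

    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    d = m + 1  # coefficient vector c: [intercept, β_1..β_m]
    c = np.zeros(d)
    c[0] = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, c[0])
    w = np.empty(n)
    q = np.empty(d)          # gradient of the log-likelihood at outer start
    H = np.empty((d, d))     # weighted Gram (Hessian of −ℓ)
    cstart = np.empty(d)

    for l in range(L):
        lam_n = n * lambdas[l]
        for outer in range(max_iter):
            iters[l] = outer + 1
            # IRLS refresh: weights w = p(1−p) (floored), gradient q, Gram H
            for jj in range(d):
                q[jj] = 0.0
                for kk in range(d):
                    H[jj, kk] = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pi * (1.0 - pi)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                ri = y[i] - pi
                q[0] += ri
                H[0, 0] += wi
                for a in range(row_ptr[i], row_ptr[i + 1]):
                    ja = row_idx[a] + 1
                    va = row_val[a]
                    q[ja] += va * ri
                    H[0, ja] += wi * va
                    for b_ in range(a, row_ptr[i + 1]):
                        jb = row_idx[b_] + 1
                        H[ja, jb] += wi * va * row_val[b_]
            for jj in range(1, d):
                H[jj, 0] = H[0, jj]
                for kk in range(jj + 1, d):
                    H[kk, jj] = H[jj, kk]
            for jj in range(d):
                cstart[jj] = c[jj]

            # inner CD on the quadratic model, entirely in coefficient space:
            # grad_j = q_j − Σ_k H_jk (c_k − cstart_k)
            for _inner in range(200):
                max_change = 0.0
                for jj in range(d):
                    hjj = H[jj, jj]
                    if hjj == 0.0:
                        continue
                    g = q[jj]
                    for kk in range(d):
                        g -= H[jj, kk] * (c[kk] - cstart[kk])
                    u = g + hjj * c[jj]
                    if jj == 0:
                        cnew = c[0] + g / hjj
                    elif u > lam_n:
                        cnew = (u - lam_n) / hjj
                    elif u < -lam_n:
                        cnew = (u + lam_n) / hjj
                    else:
                        cnew = 0.0
                    dlt = cnew - c[jj]
                    if dlt != 0.0:
                        c[jj] = cnew
                        ad = abs(dlt)
                        if ad > max_change:
                            max_change = ad
                if max_change < tol:
                    break

            # apply the Newton step to the linear predictor
            outer_change = 0.0
            d0 = c[0] - cstart[0]
            if d0 != 0.0:
                for i in range(n):
                    eta[i] += d0
                outer_change = abs(d0)
            for jj in range(1, d):
                if c[jj] != cstart[jj]:
                    ad = abs(c[jj] - cstart[jj])
                    if ad > outer_change:
                        outer_change = ad
            if outer_change > 0.0:
                for i in range(n):
                    upd = 0.0
                    for a in range(row_ptr[i], row_ptr[i + 1]):
                        jj = row_idx[a] + 1
                        if c[jj] != cstart[jj]:
                            upd += (c[jj] - cstart[jj]) * row_val[a]
                    if upd != 0.0:
                        eta[i] += upd
            if outer_change < tol:
                break
        intercepts[l] = c[0]
        for j in range(m):
            coefs[l, j] = c[j + 1]
        ll = 0.0
        for i in range(n):
            # log(1+exp(eta)) computed stably
            if eta[i] > 0.0:
                ll += y[i] * eta[i] - (eta[i] + np.log1p(np.exp(-eta[i])))
            else:
                ll += y[i] * eta[i] - np.log1p(np.exp(eta[i]))
        logliks[l] = ll
    return intercepts, coefs, logliks, iters


@njit(cache=True)
def gibbs_sample(thresholds, weights, n_samples, burn_in, thinning, seed):  # pragma: no cover - jit
    """Single-site Gibbs sampler for the Ising model on {0,1}^p.

    Full conditional: logit P(x_i=1 | x_-i) = τ_i + Σ_j ω_ij x_j.
    Systematic sweeps; one retained sample every ``thinning`` sweeps after
    ``burn_in`` sweeps.
    """
    np.random.seed(seed)
    p = thresholds.shape[0]
    x = np.empty(p)
    for i in range(p):
        x[i] = 1.0 if np.random.random() < 0.5 else 0.0
    out = np.empty((n_samples, p))
    kept = 0
    total = burn_in + n_samples * thinning
    for sweep in range(total):
        for i in range(p):
            eta = thresholds[i]
            for j in range(p):
                eta += weights[i, j] * x[j]
            pi = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1.0 if np.random.random() < pi else 0.0
        if sweep >= burn_in and (sweep - burn_in + 1) % thinning == 0:
            for i in range(p):
                out[kept, i] = x[i]
            kept += 1
    return out
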