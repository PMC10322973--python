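"""Compiled inner loop for maximum-likelihood SEM fitting.

The per-voxel pipeline evaluates the ML discrepancy tens of thousands of
times, so the objective/gradient kernel and a dense-BFGS minimiser are
numba-compiled here.  The algebra is identical to the numpy implementation in
:mod:`voxelsem.sem_core` (which remains the readable reference and is checked
against this path in the test suite); only the execution strategy differs.

All linear algebra is written out for the tiny (<= 10 x 10) matrices involved:
Gauss-Jordan inversion of (I - A) and a manual Cholesky factorisation whose
failure signals a non-PD implied covariance, returned as a barrier value so
the line search backs away instead of crashing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BARRIER = 1e12

# bfgs status codes
CONVERGED = 0
MAXITER = 1
LINE_SEARCH_FAILED = 2


@njit(cache=False, fastmath=False)
def _objgrad(theta, a_fixed, a_rows, a_cols, a_idx,
             s_fixed, s_rows, s_cols, s_idx,
             obs, s_samp, ln_det_s):
    m = a_fixed.shape[0]
    p = obs.size
    nfree = theta.size
    grad = np.zeros(nfree)

    a = a_fixed.copy()
    for k in range(a_rows.size):
        a[a_rows[k], a_cols[k]] = theta[a_idx[k]]
    s = s_fixed.copy()
    for k in range(s_rows.size):
        s[s_rows[k], s_cols[k]] = theta[s_idx[k]]
        s[s_cols[k], s_rows[k]] = theta[s_idx[k]]

    # b = (I - A)^-1 by Gauss-Jordan with partial pivoting
    w = -a
    for i in range(m):
        w[i, i] += 1.0
    b = np.eye(m)
    for col in range(m):
        piv = col
        big = abs(w[col, col])
        for r in range(col + 1, m):
            if abs(w[r, col]) > big:
                big = abs(w[r, col])
                piv = r
        if big < 1e-300:
            return _BARRIER, grad
        if piv != col:
            for c in range(m):
                w[piv, c], w[col, c] = w[col, c], w[piv, c]
                b[piv, c], b[col, c] = b[col, c], b[piv, c]
        d = w[col, col]
        for c in range(m):
            w[col, c] /= d
            b[col, c] /= d
        for r in range(m):
            if r != col:
                f = w[r, col]
                if f != 0.0:
                    for c in range(m):
                        w[r, c] -= f * w[col, c]
                        b[r, c] -= f * b[col, c]

    v = b @ s @ b.T
    sigma = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            sigma[i, j] = v[obs[i], obs[j]]

    # Cholesky; failure = implied covariance not PD
    chol = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1):
            acc = sigma[i, j]
            for k in range(j):
                acc -= chol[i, k] * chol[j, k]
            if i == j:
                if acc <= 0.0:
                    return _BARRIER, grad
                chol[i, i] = np.sqrt(acc)
            else:
                chol[i, j] = acc / chol[j, j]

    ln_det = 0.0
    for i in range(p):
        ln_det += np.log(chol[i, i])
    ln_det *= 2.0

    # sigma^-1 from the factor
    sigma_inv = np.zeros((p, p))
    for col in range(p):
        y = np.zeros(p)
        for i in range(p):
            acc = 1.0 if i == col else 0.0
            for k in range(i):
                acc -= chol[i, k] * y[k]
            y[i] = acc / chol[i, i]
        for i in range(p - 1, -1, -1):
            acc = y[i]
            for k in range(i + 1, p):
                acc -= chol[k, i] * sigma_inv[k, col]
            sigma_inv[i, col] = acc / chol[i, i]

    f = ln_det - ln_det_s - p
    for i in range(p):
        for j in range(p):
            f += sigma_inv[i, j] * s_samp[j, i]
    if not np.isfinite(f):
        return _BARRIER, grad

    # dF = tr[(sigma^-1 - sigma^-1 S sigma^-1) dSigma]
    g_obs = sigma_inv - sigma_inv @ s_samp @ sigma_inv
    g_full = np.zeros((m, m))
    for i in range(p):
        for j in range(p):
            g_full[obs[i], obs[j]] = g_obs[i, j]

    bt_g = b.T @ g_full
    pa = bt_g @ v
    for k in range(a_rows.size):
        grad[a_idx[k]] += 2.0 * pa[a_rows[k], a_cols[k]]
    ms = bt_g @ b
    for k in range(s_rows.size):
        wgt = 1.0 if s_rows[k] == s_cols[k] else 2.0
        grad[s_idx[k]] += wgt * ms[s_rows[k], s_cols[k]]
    return f, grad


@njit(cache=False)
def _nelder_mead(x0, scale, maxfev,
                 a_fixed, a_rows, a_cols, a_idx,
                 s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s):
    """Adaptive Nelder-Mead (Gao-Han coefficients) on the SEM discrepancy.

    Used as a rescue stage for fits whose gradient-based runs stall: simplex
    search tolerates the barrier-adjacent, locally flat surfaces that
    misspecified models produce.  Returns the best vertex and its value.
    """
    n = x0.size
    rho = 1.0
    chi = 1.0 + 2.0 / n
    psi = 0.75 - 1.0 / (2.0 * n)
    sigma = 1.0 - 1.0 / n

    m = n + 1
    simplex = np.empty((m, n))
    fvals = np.empty(m)
    for i in range(m):
        simplex[i] = x0
        if i > 0:
            d = scale * max(abs(x0[i - 1]), 0.25)
            simplex[i, i - 1] += d
        f, _ = _objgrad(simplex[i], a_fixed, a_rows, a_cols, a_idx,
                        s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s)
        fvals[i] = f
    nfev = m

    while nfev < maxfev:
        order = np.argsort(fvals)
        simplex = simplex[order]
        fvals = fvals[order]
        if fvals[-1] - fvals[0] < 1e-12 * (abs(fvals[0]) + 1e-12):
            break
        centroid = np.zeros(n)
        for i in range(n):
            for j in range(n):
                centroid[j] += simplex[i, j]
        centroid /= n

        xr = centroid + rho * (centroid - simplex[-1])
        fr, _ = _objgrad(xr, a_fixed, a_rows, a_cols, a_idx,
                         s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s)
        nfev += 1
        if fr < fvals[0]:
            xe = centroid + chi * rho * (centroid - simplex[-1])
            fe, _ = _objgrad(xe, a_fixed, a_rows, a_cols, a_idx,
                             s_fixed, s_rows, s_cols, s_idx, obs, s_samp,
                             ln_det_s)
            nfev += 1
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = centroid + psi * rho * (centroid - simplex[-1])
            else:               # inside contraction
                xc = centroid - psi * (centroid - simplex[-1])
            fc, _ = _objgrad(xc, a_fixed, a_rows, a_cols, a_idx,
                             s_fixed, s_rows, s_cols, s_idx, obs, s_samp,
                             ln_det_s)
            nfev += 1
            if fc < min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fc
            else:               # shrink toward the best vertex
                for i in range(1, m):
                    simplex[i] = simplex[0] + sigma * (simplex[i] - simplex[0])
                    f, _ = _objgrad(simplex[i], a_fixed, a_rows, a_cols,
                                    a_idx, s_fixed, s_rows, s_cols, s_idx,
                                    obs, s_samp, ln_det_s)
                    fvals[i] = f
                nfev += n
    best = np.argmin(fvals)
    return simplex[best], fvals[best]


_C1 = 1e-4   # sufficient-decrease constant
_C2 = 0.9    # curvature constant


@njit(cache=False)
def _phi(x, d, alpha, a_fixed, a_rows, a_cols, a_idx,
         s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s):
    f, g = _objgrad(x + alpha * d, a_fixed, a_rows, a_cols, a_idx,
                    s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s)
    dphi = 0.0
    for i in range(d.size):
        dphi += g[i] * d[i]
    return f, dphi, g


@njit(cache=False)
def _zoom(x, d, a_lo, a_hi, f_lo, f_hi, d_lo, f0, dphi0,
          a_fixed, a_rows, a_cols, a_idx, s_fixed, s_rows, s_cols, s_idx,
          obs, s_samp, ln_det_s):
    """Wolfe zoom stage (bisection with quadratic interpolation)."""
    g_j = np.zeros(x.size)
    for _ in range(30):
        # quadratic interpolation between lo and hi, safeguarded
        denom = f_hi - f_lo - d_lo * (a_hi - a_lo)
        if abs(denom) > 1e-300:
            a_j = a_lo + 0.5 * d_lo * (a_hi - a_lo) ** 2 / (
                f_lo - f_hi + d_lo * (a_hi - a_lo))
        else:
            a_j = 0.5 * (a_lo + a_hi)
        lo, hi = min(a_lo, a_hi), max(a_lo, a_hi)
        if not (lo + 0.05 * (hi - lo) <= a_j <= hi - 0.05 * (hi - lo)):
            a_j = 0.5 * (a_lo + a_hi)
        f_j, d_j, g_j = _phi(x, d, a_j, a_fixed, a_rows, a_cols, a_idx,
                             s_fixed, s_rows, s_cols, s_idx,
                             obs, s_samp, ln_det_s)
        if (f_j > f0 + _C1 * a_j * dphi0) or (f_j >= f_lo):
            a_hi, f_hi = a_j, f_j
        else:
            if abs(d_j) <= -_C2 * dphi0:
                return a_j, f_j, g_j, True
            if d_j * (a_hi - a_lo) >= 0.0:
                a_hi, f_hi = a_lo, f_lo
            a_lo, f_lo, d_lo = a_j, f_j, d_j
        if abs(a_hi - a_lo) < 1e-16 * max(1.0, abs(a_lo)):
            return a_lo, f_lo, g_j, f_lo < f0
    return a_lo, f_lo, g_j, f_lo < f0 + _C1 * a_lo * dphi0


@njit(cache=False)
def _wolfe(x, d, f0, dphi0, g0, a_fixed, a_rows, a_cols, a_idx,
           s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s):
    """Strong-Wolfe line search (bracketing stage)."""
    a_prev = 0.0
    f_prev = f0
    d_prev = dphi0
    alpha = 1.0
    g_best = g0
    for it in range(25):
        f_a, d_a, g_a = _phi(x, d, alpha, a_fixed, a_rows, a_cols, a_idx,
                             s_fixed, s_rows, s_cols, s_idx,
                             obs, s_samp, ln_det_s)
        g_best = g_a
        if (f_a > f0 + _C1 * alpha * dphi0) or (it > 0 and f_a >= f_prev):
            return _zoom(x, d, a_prev, alpha, f_prev, f_a, d_prev, f0, dphi0,
                         a_fixed, a_rows, a_cols, a_idx,
                         s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s)
        if abs(d_a) <= -_C2 * dphi0:
            return alpha, f_a, g_a, True
        if d_a >= 0.0:
            return _zoom(x, d, alpha, a_prev, f_a, f_prev, d_a, f0, dphi0,
                         a_fixed, a_rows, a_cols, a_idx,
                         s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s)
        a_prev, f_prev, d_prev = alpha, f_a, d_a
        alpha *= 2.5
    return a_prev, f_prev, g_best, f_prev < f0 + _C1 * a_prev * dphi0


@njit(cache=False)
def _bfgs(theta0, a_fixed, a_rows, a_cols, a_idx,
          s_fixed, s_rows, s_cols, s_idx,
          obs, s_samp, ln_det_s, gtol, maxiter):
    """Dense BFGS with a strong-Wolfe line search on the SEM discrepancy.

    Returns (theta, f, grad, n_iter, status) with status CONVERGED / MAXITER /
    LINE_SEARCH_FAILED.  Curvature-violating steps skip the Hessian update
    (standard damped practice), keeping the inverse-Hessian approximation PD;
    the initial inverse Hessian is rescaled to the first step's curvature.
    """
    n = theta0.size
    x = theta0.copy()
    f, g = _objgrad(x, a_fixed, a_rows, a_cols, a_idx,
                    s_fixed, s_rows, s_cols, s_idx, obs, s_samp, ln_det_s)
    h = np.eye(n)
    status = MAXITER
    it = 0
    first_update = True
    while it < maxiter:
        gmax = 0.0
        for i in range(n):
            if abs(g[i]) > gmax:
                gmax = abs(g[i])
        if gmax <= gtol:
            status = CONVERGED
            break
        d = -(h @ g)
        gd = 0.0
        for i in range(n):
            gd += g[i] * d[i]
        if gd >= 0.0:  # not a descent direction: reset to steepest descent
            h = np.eye(n)
            first_update = True
            d = -g
            gd = -g @ g
        alpha, fn, gn, ok = _wolfe(x, d, f, gd, g,
                                   a_fixed, a_rows, a_cols, a_idx,
                                   s_fixed, s_rows, s_cols, s_idx,
                                   obs, s_samp, ln_det_s)
        if (not ok) or not np.isfinite(fn) or fn >= f:
            # no acceptable step: flat to machine precision counts converged
            status = CONVERGED if gmax <= 1e-4 else LINE_SEARCH_FAILED
            break
        xn = x + alpha * d
        sv = xn - x
        yv = gn - g
        sy = 0.0
        for i in range(n):
            sy += sv[i] * yv[i]
        if sy > 1e-10 * np.sqrt((sv @ sv) * (yv @ yv)):
            if first_update:
                yy = yv @ yv
                if yy > 0.0:
                    scale = sy / yy
                    for i in range(n):
                        h[i, i] = scale
                first_update = False
            rho = 1.0 / sy
            hy = h @ yv
            yhy = yv @ hy
            # BFGS inverse update: H += (sy + yHy) ss^T rho^2 - rho (Hy s^T + s yH^T)
            c1 = (sy + yhy) * rho * rho
            for i in range(n):
                for j in range(n):
                    h[i, j] += c1 * sv[i] * sv[j] - rho * (hy[i] * sv[j] + sv[i] * hy[j])
        x, f, g = xn, fn, gn
        it += 1
    return x, f, g, it, status
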