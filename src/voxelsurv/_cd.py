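"""Numba kernel for weighted-least-squares lasso coordinate descent.

Solves  min_beta  sum_i w_i (z_i - eta_i)^2 + lam * sum_j |beta_j|
with eta = XT.T @ beta maintained incrementally. ``w`` already carries the
family- and sample-size-dependent scaling, so the soft-threshold level is
``lam`` itself. Full sweeps alternate with active-set sweeps (glmnet
strategy). Convergence uses two criteria, whichever comes first: the
maximum coefficient change below ``tol``, or the maximum energy change
``a_j * delta_j^2`` below ``etol`` — the latter is what terminates on
nearly collinear column groups (e.g. modulated vs unmodulated channels),
where coefficient mass keeps shuffling between duplicates long after the
fit itself has stopped moving.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep(XT, w, z, eta, beta, a, lam, active_only):
    p, n = XT.shape
    max_change = 0.0
    max_energy = 0.0
    for j in range(p):
        if a[j] <= 0.0:
            continue
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        c = a[j] * bj
        for i in range(n):
            c += w[i] * XT[j, i] * (z[i] - eta[i])
        if c > lam:
            bnew = (c - lam) / a[j]
        elif c < -lam:
            bnew = (c + lam) / a[j]
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            for i in range(n):
                eta[i] += d * XT[j, i]
            beta[j] = bnew
            ad = abs(d)
            if ad > max_change:
                max_change = ad
            e = a[j] * d * d
            if e > max_energy:
                max_energy = e
    return max_change, max_energy


@njit(cache=True)
def wls_lasso(XT, w, z, eta, beta, lam, tol, etol, max_sweeps):
    p, n = XT.shape
    a = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * XT[j, i] * XT[j, i]
        a[j] = s
    sweeps = 0
    while sweeps < max_sweeps:
        mc, me = _sweep(XT, w, z, eta, beta, a, lam, False)
        sweeps += 1
        if mc < tol or me < etol:
            return sweeps
        while sweeps < max_sweeps:
            mc, me = _sweep(XT, w, z, eta, beta, a, lam, True)
            sweeps += 1
            if mc < tol or me < etol:
                break
    return sweeps
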