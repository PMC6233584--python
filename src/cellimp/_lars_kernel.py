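"""Compiled LARS-lasso path on a precomputed Gram matrix.

The homotopy algorithm for the lasso: starting from the empty model, track
the piecewise-linear coefficient path in the penalty, adding the predictor
whose absolute correlation ties the active maximum and dropping any active
coefficient that crosses zero.  Correlations are maintained incrementally
from the Gram matrix (c = Xy - G beta), and the active-set normal matrix
is kept as an updatable Cholesky factor, so one step costs O(p k + k^2).

Used by the neighbor pre-selection stage, where thousands of paths over
the same (column-deleted) Gram matrices are needed and per-step overhead
dominates any generic implementation.  Breakpoints are returned in
sklearn's convention (alpha = max|c| / n_samples) so the caller can
interpolate the path, which is exactly piecewise linear, onto any alpha
grid.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def lars_lasso_gram(G, Xy, n_samples, alpha_min, max_steps):
    """LARS-lasso path from a Gram matrix.

    Returns (alphas, coefs, n_bp): breakpoint penalties (decreasing, scaled
    by 1/n_samples), coefficients at each breakpoint (n_bp x p), and the
    breakpoint count.  The path stops at alpha_min, after max_steps, or
    when the active set saturates.
    """
    p = Xy.shape[0]
    max_active = min(p, n_samples - 1, max_steps)
    c = Xy.copy()
    beta = np.zeros(p)
    excluded = np.zeros(p, dtype=np.bool_)
    in_active = np.zeros(p, dtype=np.bool_)
    active = np.empty(max_active, dtype=np.int64)
    sgn = np.empty(max_active)
    n_act = 0
    R = np.zeros((max_active, max_active))  # upper triangular: R^T R = G_AA

    out_alphas = np.empty(max_steps + 2)
    out_coefs = np.zeros((max_steps + 2, p))
    C = 0.0
    for j in range(p):
        a = abs(c[j])
        if a > C:
            C = a
    out_alphas[0] = C / n_samples
    n_bp = 1
    target = alpha_min * n_samples

    w = np.empty(max_active)
    d = np.empty(max_active)
    a_all = np.empty(p)

    steps = 0
    while steps < max_steps and C > target + 1e-15 and n_act < max_active:
        steps += 1
        # --- add the inactive predictor whose |c| attains C
        jbest = -1
        cbest = -1.0
        for j in range(p):
            if not in_active[j] and not excluded[j]:
                a = abs(c[j])
                if a > cbest:
                    cbest = a
                    jbest = j
        if jbest < 0 or cbest <= 1e-14:
            break
        C = cbest
        if C <= target + 1e-15:
            break
        # Cholesky append: R^T w = G[active, jbest]
        ok = True
        for i in range(n_act):
            s = G[active[i], jbest]
            for k2 in range(i):
                s -= R[k2, i] * w[k2]
            w[i] = s / R[i, i]
        s = G[jbest, jbest]
        for k2 in range(n_act):
            s -= w[k2] * w[k2]
        if s <= 1e-12:
            excluded[jbest] = True  # collinear with the active set
            continue
        for i in range(n_act):
            R[i, n_act] = w[i]
        R[n_act, n_act] = math.sqrt(s)
        active[n_act] = jbest
        sgn[n_act] = 1.0 if c[jbest] > 0 else -1.0
        in_active[jbest] = True
        n_act += 1

        while True:
            # --- equiangular direction: G_AA d = sgn  (two triangular solves)
            for i in range(n_act):
                s = sgn[i]
                for k2 in range(i):
                    s -= R[k2, i] * w[k2]
                w[i] = s / R[i, i]
            for i in range(n_act - 1, -1, -1):
                s = w[i]
                for k2 in range(i + 1, n_act):
                    s -= R[i, k2] * d[k2]
                d[i] = s / R[i, i]
            # a_j = G[j, active] @ d for every j
            for j in range(p):
                a_all[j] = 0.0
            for i in range(n_act):
                ai = active[i]
                di = d[i]
                for j in range(p):      # row access: G is symmetric
                    a_all[j] += G[ai, j] * di
            # --- step length
            gamma = C - target  # stop exactly at alpha_min
            for j in range(p):
                if in_active[j] or excluded[j]:
                    continue
                aj = a_all[j]
                num1 = C - c[j]
                den1 = 1.0 - aj
                if den1 > 1e-14:
                    g1 = num1 / den1
                    if 1e-14 < g1 < gamma:
                        gamma = g1
                num2 = C + c[j]
                den2 = 1.0 + aj
                if den2 > 1e-14:
                    g2 = num2 / den2
                    if 1e-14 < g2 < gamma:
                        gamma = g2
            drop_i = -1
            for i in range(n_act):
                if d[i] != 0.0:
                    g = -beta[active[i]] / d[i]
                    if 1e-14 < g < gamma:
                        gamma = g
                        drop_i = i
            # --- advance
            for i in range(n_act):
                beta[active[i]] += gamma * d[i]
            for j in range(p):
                c[j] -= gamma * a_all[j]
            C -= gamma
            if drop_i >= 0:
                beta[active[drop_i]] = 0.0
            out_alphas[n_bp] = C / n_samples
            for j in range(p):
                out_coefs[n_bp, j] = beta[j]
            n_bp += 1
            if drop_i < 0:
                break  # a new tie was reached: go add the next predictor
            # --- lasso drop: remove the crossing coefficient, refactor, and
            # keep moving along the reduced active set (no addition)
            jdrop = active[drop_i]
            in_active[jdrop] = False
            for i in range(drop_i, n_act - 1):
                active[i] = active[i + 1]
                sgn[i] = sgn[i + 1]
            n_act -= 1
            for i in range(n_act):      # rebuild Cholesky of the reduced set
                for k2 in range(i, n_act):
                    s = G[active[i], active[k2]]
                    for m in range(i):
                        s -= R[m, i] * R[m, k2]
                    if k2 == i:
                        R[i, i] = math.sqrt(max(s, 1e-15))
                    else:
                        R[i, k2] = s / R[i, i]
            steps += 1
            if (steps >= max_steps or n_bp >= out_alphas.shape[0] - 1
                    or C <= target + 1e-15 or n_act == 0):
                break
    return out_alphas[:n_bp], out_coefs[:n_bp], n_bp
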