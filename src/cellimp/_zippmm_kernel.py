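"""Compiled inner loops for the zero-inflated Poisson-lognormal EM.

One gene at a time, all scalars: the E-step responsibilities, the damped
2-D Newton M-step on (mu, log psi), and a SQUAREM-style extrapolation with
an observed-likelihood safeguard.  The quadrature mixture density is

    A_l(c) = sum_k omega_k Poisson(c; N_l exp(mu + sqrt(2 psi) x_k)),

with (x_k, omega_k) fixed Gauss-Hermite nodes/weights.  Everything is in
the log domain with max-shifted sums, so extreme rates do not underflow.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

P_CAP = 0.99
MU_FLOOR = -30.0
MU_CEIL = 10.0
PSI_MIN = 1e-6
PSI_MAX = 50.0


@njit(cache=False)
def _log_mix_row(c, lgam, logN, mu, sq, gh_x, log_w, lt):
    """log A_l(c) for one neighbor; lt is scratch of size K."""
    K = gh_x.shape[0]
    m = -1.0e308
    for k in range(K):
        eta = logN + mu + sq * gh_x[k]
        t = log_w[k] + c * eta - math.exp(eta) - lgam
        lt[k] = t
        if t > m:
            m = t
    s = 0.0
    for k in range(K):
        s += math.exp(lt[k] - m)
    return m + math.log(s)


@njit(cache=False)
def _q_of(counts_g, lgam_g, log_depths, mu, psi, w, lt):
    L = counts_g.shape[0]
    sq = math.sqrt(2.0 * psi)
    Q = 0.0
    for l in range(L):
        if w[l] > 0.0:
            Q += w[l] * _log_mix_row(counts_g[l], lgam_g[l], log_depths[l], mu, sq,
                                     _GH_X, _LOG_W, lt)
    return Q


@njit(cache=False)
def _q_grad_hess(counts_g, lgam_g, log_depths, mu, psi, w, lt):
    """Q, gradient and Hessian wrt (mu, u = log psi) for one gene."""
    L = counts_g.shape[0]
    K = _GH_X.shape[0]
    sq = math.sqrt(2.0 * psi)
    Q = 0.0
    gmu = 0.0
    gu = 0.0
    hmm = 0.0
    hmu = 0.0
    huu = 0.0
    for l in range(L):
        wl = w[l]
        if wl <= 0.0:
            continue
        c = counts_g[l]
        logN = log_depths[l]
        m = -1.0e308
        for k in range(K):
            eta = logN + mu + sq * _GH_X[k]
            t = _LOG_W[k] + c * eta - math.exp(eta) - lgam_g[l]
            lt[k] = t
            if t > m:
                m = t
        s = 0.0
        for k in range(K):
            s += math.exp(lt[k] - m)
        logA = m + math.log(s)
        # posterior node moments
        amu = 0.0
        au = 0.0
        smm = 0.0
        smu_ = 0.0
        suu = 0.0
        for k in range(K):
            pi = math.exp(lt[k] - m) / s
            eta = logN + mu + sq * _GH_X[k]
            e = math.exp(eta)
            a = 0.5 * sq * _GH_X[k]         # d eta / d u
            tm = c - e                      # d logpois / d mu
            tu = tm * a
            amu += pi * tm
            au += pi * tu
            smm += pi * (-e + tm * tm)
            smu_ += pi * (-e * a + tm * tu)
            suu += pi * (-e * a * a + tm * a * 0.5 + tu * tu)
        Q += wl * logA
        gmu += wl * amu
        gu += wl * au
        hmm += wl * (smm - amu * amu)
        hmu += wl * (smu_ - amu * au)
        huu += wl * (suu - au * au)
    return Q, gmu, gu, hmm, hmu, huu


@njit(cache=False)
def _newton_mu_psi(counts_g, lgam_g, log_depths, mu, psi, w, tol, lt, max_inner):
    Q0, gmu, gu, hmm, hmu, huu = _q_grad_hess(counts_g, lgam_g, log_depths, mu, psi, w, lt)
    for _ in range(max_inner):
        det = hmm * huu - hmu * hmu
        if hmm < 0.0 and det > 0.0:
            smu = (-gmu * huu + gu * hmu) / det
            su = (-gu * hmm + gmu * hmu) / det
        else:
            smu = 0.25 if gmu > 0 else (-0.25 if gmu < 0 else 0.0)
            su = 0.25 if gu > 0 else (-0.25 if gu < 0 else 0.0)
        if smu > 3.0:
            smu = 3.0
        elif smu < -3.0:
            smu = -3.0
        if su > 3.0:
            su = 3.0
        elif su < -3.0:
            su = -3.0
        accepted = False
        for _bt in range(8):
            mu_t = min(max(mu + smu, MU_FLOOR), MU_CEIL)
            psi_t = min(max(psi * math.exp(su), PSI_MIN), PSI_MAX)
            Qt = _q_of(counts_g, lgam_g, log_depths, mu_t, psi_t, w, lt)
            if Qt >= Q0 - 1e-12:
                mu, psi = mu_t, psi_t
                accepted = True
                break
            smu *= 0.5
            su *= 0.5
        if not accepted:
            break
        Q1, gmu, gu, hmm, hmu, huu = _q_grad_hess(counts_g, lgam_g, log_depths, mu, psi, w, lt)
        gain = Q1 - Q0
        Q0 = Q1
        if gain <= 0.1 * tol:
            break
    return mu, psi


@njit(cache=False)
def _em_step(counts_g, lgam_g, log_depths, p, mu, psi, logA_cache, tol, lt):
    """One EM step; logA_cache holds log A_l at the incoming (mu, psi)."""
    L = counts_g.shape[0]
    rsum = 0.0
    w = np.empty(L)
    lp = math.log(max(p, 1e-300))
    l1p = math.log1p(-min(p, 1.0 - 1e-300))
    for l in range(L):
        if counts_g[l] == 0:
            a = lp
            b = l1p + logA_cache[l]
            hi = a if a > b else b
            den = hi + math.log(math.exp(a - hi) + math.exp(b - hi))
            r = math.exp(lp - den)
        else:
            r = 0.0
        w[l] = 1.0 - r
        rsum += r
    p_new = rsum / L
    if p_new > P_CAP:
        p_new = P_CAP
    mu_new, psi_new = _newton_mu_psi(counts_g, lgam_g, log_depths, mu, psi, w, tol, lt, 4)
    return p_new, mu_new, psi_new


@njit(cache=False)
def _obs_ll(counts_g, lgam_g, log_depths, p, mu, psi, logA_out, lt):
    """Observed log-likelihood; also refreshes the logA cache at (mu, psi)."""
    L = counts_g.shape[0]
    sq = math.sqrt(2.0 * psi)
    lp = math.log(max(p, 1e-300))
    l1p = math.log1p(-min(p, 1.0 - 1e-300))
    ll = 0.0
    for l in range(L):
        la = _log_mix_row(counts_g[l], lgam_g[l], log_depths[l], mu, sq, _GH_X, _LOG_W, lt)
        logA_out[l] = la
        if counts_g[l] == 0:
            a = lp
            b = l1p + la
            hi = a if a > b else b
            ll += hi + math.log(math.exp(a - hi) + math.exp(b - hi))
        else:
            ll += l1p + la
    return ll


@njit(cache=False)
def em_fit_genes(counts, lgam, log_depths, p0, mu0, psi0, skip, tol, max_iter,
                 p_out, mu_out, psi_out, ll_out, n_iter, converged, trace):
    """Fit every gene; trace[t, g] records the log-likelihood path."""
    G, L = counts.shape
    K = _GH_X.shape[0]
    lt = np.empty(K)
    logA = np.empty(L)
    logA2 = np.empty(L)
    for g in range(G):
        if skip[g]:
            n_iter[g] = 0
            converged[g] = True
            continue
        p = p0[g]
        mu = mu0[g]
        psi = psi0[g]
        cg = counts[g]
        lg = lgam[g]
        ll_prev = -1.0e300
        ll = ll_prev
        it = 0
        conv = False
        # prime the logA cache at the initial parameters
        _obs_ll(cg, lg, log_depths, p, mu, psi, logA, lt)
        while it < max_iter:
            # two EM steps
            p1, mu1, psi1 = _em_step(cg, lg, log_depths, p, mu, psi, logA, tol, lt)
            ll1 = _obs_ll(cg, lg, log_depths, p1, mu1, psi1, logA, lt)
            p2, mu2, psi2 = _em_step(cg, lg, log_depths, p1, mu1, psi1, logA, tol, lt)
            ll2 = _obs_ll(cg, lg, log_depths, p2, mu2, psi2, logA, lt)
            it += 2
            # SQUAREM extrapolation in (p, mu, log psi), safeguarded
            r0 = p1 - p
            r1 = mu1 - mu
            r2 = math.log(psi1) - math.log(psi)
            v0 = (p2 - p1) - r0
            v1 = (mu2 - mu1) - r1
            v2 = (math.log(psi2) - math.log(psi1)) - r2
            rn = math.sqrt(r0 * r0 + r1 * r1 + r2 * r2)
            vn = math.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
            alpha = -1.0 if vn <= 0.0 else -rn / vn
            if alpha > -1.0:
                alpha = -1.0
            elif alpha < -50.0:
                alpha = -50.0
            px = p - 2.0 * alpha * r0 + alpha * alpha * v0
            mux = mu - 2.0 * alpha * r1 + alpha * alpha * v1
            ux = math.log(psi) - 2.0 * alpha * r2 + alpha * alpha * v2
            px = min(max(px, 0.0), P_CAP)
            mux = min(max(mux, MU_FLOOR), MU_CEIL)
            psix = min(max(math.exp(ux), PSI_MIN), PSI_MAX)
            llx = _obs_ll(cg, lg, log_depths, px, mux, psix, logA2, lt)
            if llx >= ll2 and math.isfinite(llx):
                p, mu, psi, ll = px, mux, psix, llx
                for l in range(L):
                    logA[l] = logA2[l]
            else:
                p, mu, psi, ll = p2, mu2, psi2, ll2
            t_idx = it // 2 - 1
            if t_idx < trace.shape[0]:
                trace[t_idx, g] = ll
            if abs(ll - ll_prev) < tol:
                conv = True
                break
            ll_prev = ll
        p_out[g] = p
        mu_out[g] = mu
        psi_out[g] = psi
        ll_out[g] = ll
        n_iter[g] = it
        converged[g] = conv


_GH_X, _gh_w = np.polynomial.hermite.hermgauss(31)
_LOG_W = np.log(_gh_w / np.sqrt(np.pi))
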