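"""Dropout adjustment via a zero-inflated Poisson mixed (log-normal) model.

A zero count in a neighbor cell is ambiguous: it may be a dropout (the
transcript was present but not captured) or genuine low/zero expression.
Before a neighbor's value is used as a predictor for imputation, zeros are
replaced by an estimate of the underlying expression rate under

    C_l ~ p * delta_0 + (1 - p) * PoissonLN(N_l * lambda_l, psi),

where, for one gene within one target cell's neighborhood, p is the shared
dropout probability, N_l the neighbor's read depth, and the Poisson
mixed-effects component is realized as a log-normal rate mixture:
lambda_l = exp(mu + eps_l) with eps_l ~ Normal(0, psi).  The integral over
eps is evaluated with fixed 31-point Gauss-Hermite quadrature, i.e. the
working likelihood is the corresponding finite Poisson mixture — a proper
density, so the EM ascent property holds exactly for it.

EM structure: the E-step computes posterior dropout responsibilities for
zero counts; the M-step updates p in closed form (capped at 0.99 to avoid
the degenerate all-dropout solution) and (mu, psi) by damped Newton ascent
on (mu, log psi) with backtracking that never accepts a decrease of the
expected complete-data log-likelihood.  Iterations are taken in blocks of
two EM steps plus a SQUAREM-style extrapolation accepted only when the
observed log-likelihood does not decrease.  All genes of one neighborhood
are fitted in one compiled pass (arrays are genes x neighbors).

The final predictor for a zero count is the posterior mean of lambda_l
marginalized over the dropout indicator, mapped back to the log-RPM scale
as ln(1e6 * lambda + 0.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from ._zippmm_kernel import em_fit_genes

logger = logging.getLogger(__name__)

N_QUAD = 31
_gh_x, _gh_w = np.polynomial.hermite.hermgauss(N_QUAD)
GH_NODES = _gh_x            # x_k
GH_WEIGHTS = _gh_w / np.sqrt(np.pi)   # omega_k, sum to 1
_LOG_GH_W = np.log(GH_WEIGHTS)[None, None, :]

P_CAP = 0.99
MU_FLOOR = -30.0
PSI_MIN = 1e-6
PSI_MAX = 50.0


@dataclass
class DropoutFit:
    """Fitted dropout model for one gene within one neighborhood."""

    target_cell: int
    gene: int
    p: float
    mu: float
    psi: float
    lambda_hat: np.ndarray          # posterior-mean rate per neighbor (zeros adjusted)
    loglik_trace: np.ndarray
    converged: bool
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    depths: np.ndarray = field(default_factory=lambda: np.empty(0))



def fit_zip_pmm_genes(
    counts: np.ndarray,
    depths: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> dict:
    """Fit the ZIP-PMM to many genes of one neighborhood at once.

    counts: (G, L) integer matrix (gene x neighbor); depths: (L,).
    Returns a dict of per-gene arrays: p, mu, psi, loglik_trace (one row per
    two-step EM block, frozen at the final value after per-gene
    convergence), converged, n_iter (EM steps taken), all_zero.
    """
    counts = np.atleast_2d(np.asarray(counts))
    depths = np.asarray(depths, dtype=float)
    G, L = counts.shape
    if L < 2:
        raise ValueError(f"need at least 2 neighbors, got {L}")
    if np.any(depths <= 0):
        raise ValueError("all neighbor depths must be positive")

    log_depths = np.log(depths)
    lgamma = gammaln(counts + 1.0)
    zero = counts == 0
    zero_frac = zero.mean(axis=1)
    all_zero = zero.all(axis=1)
    if all_zero.any():
        logger.warning("%d gene(s) with all-zero neighbor counts; returning capped fit", all_zero.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        nz_sum = np.where(~zero, counts / depths[None, :], 0.0).sum(axis=1)
        nz_n = (~zero).sum(axis=1)
        mu = np.log(np.where(nz_n > 0, nz_sum / np.maximum(nz_n, 1), np.exp(MU_FLOOR)))
    mu = np.where(all_zero, MU_FLOOR, np.clip(mu, MU_FLOOR, 10.0))
    psi = np.full(G, 0.5)
    p = np.clip(zero_frac * 0.5, 0.0, P_CAP)
    p = np.where(all_zero, P_CAP, p)

    # compiled EM (SQUAREM-accelerated, monotonicity-safeguarded) per gene
    counts64 = np.ascontiguousarray(counts, dtype=np.float64)
    p_out = np.ascontiguousarray(p, dtype=np.float64)
    mu_out = np.ascontiguousarray(mu, dtype=np.float64)
    psi_out = np.ascontiguousarray(psi, dtype=np.float64)
    ll_out = np.full(G, np.nan)
    n_iter = np.zeros(G, dtype=np.int64)
    converged = np.zeros(G, dtype=np.bool_)
    n_blocks = max(1, (max_iter + 1) // 2)
    trace = np.full((n_blocks, G), np.nan)
    em_fit_genes(
        counts64, np.ascontiguousarray(lgamma), log_depths,
        p_out.copy(), mu_out.copy(), psi_out.copy(), all_zero,
        tol, max_iter, p_out, mu_out, psi_out, ll_out, n_iter, converged, trace,
    )
    p = np.where(all_zero, P_CAP, p_out)
    mu = np.where(all_zero, MU_FLOOR, mu_out)
    psi = np.where(all_zero, 0.5, psi_out)
    converged = converged | all_zero

    # freeze each gene's trace at its final log-likelihood past convergence
    used = int(np.max(np.ceil(n_iter / 2))) if G else 0
    trace = trace[:max(used, 0)]
    for g in range(G):
        k = int(np.ceil(n_iter[g] / 2))
        if k < trace.shape[0]:
            trace[k:, g] = ll_out[g] if np.isfinite(ll_out[g]) else np.nan

    return {
        "p": p,
        "mu": mu,
        "psi": psi,
        "loglik_trace": trace,
        "converged": converged,
        "n_iter": n_iter,
        "all_zero": all_zero,
    }


def posterior_lambda_matrix(p, mu, psi, counts, depths) -> np.ndarray:
    """Posterior-mean rate lambda_hat for every (gene, neighbor) entry.

    For zero counts the dropout indicator is marginalized:
    E[lambda | c=0] = r * E_prior[lambda] + (1-r) * E[lambda | c=0, no dropout];
    for positive counts it is the plain posterior mean given the count.
    counts: (G, L); returns (G, L).
    """
    counts = np.atleast_2d(np.asarray(counts))
    depths = np.asarray(depths, dtype=float)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    log_depths = np.log(depths)
    lgamma = gammaln(counts + 1.0)

    shift = np.sqrt(2.0 * psi)[:, None] * GH_NODES[None, :]
    lam_nodes = np.exp(mu[:, None] + shift)                       # (G, K)
    prior_mean = (GH_WEIGHTS[None, :] * lam_nodes).sum(axis=1)    # (G,)

    eta = log_depths[None, :, None] + mu[:, None, None] + shift[:, None, :]
    logpois = counts[:, :, None] * eta - np.exp(eta) - lgamma[:, :, None]
    logterms = logpois + np.log(GH_WEIGHTS)[None, None, :]
    logA = logsumexp(logterms, axis=2)
    pi = np.exp(logterms - logA[:, :, None])
    cond_mean = (pi * lam_nodes[:, None, :]).sum(axis=2)          # (G, L)

    zero = counts == 0
    with np.errstate(divide="ignore"):
        log_p = np.log(np.maximum(p, 1e-300))[:, None]
        log_1mp = np.log1p(-np.minimum(p, 1 - 1e-300))[:, None]
    r = np.where(zero, np.exp(log_p - np.logaddexp(log_p, log_1mp + logA)), 0.0)
    return np.where(zero, r * prior_mean[:, None] + (1.0 - r) * cond_mean, cond_mean)


def fit_zip_pmm(
    counts: np.ndarray,
    depths: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    target_cell: int = -1,
    gene: int = -1,
) -> DropoutFit:
    """Fit the model for a single gene; see :func:`fit_zip_pmm_genes`."""
    counts = np.asarray(counts)
    depths = np.asarray(depths, dtype=float)
    res = fit_zip_pmm_genes(counts[None, :], depths, tol=tol, max_iter=max_iter)
    lam = posterior_lambda_matrix(res["p"], res["mu"], res["psi"], counts[None, :], depths)[0]
    trace = res["loglik_trace"][:, 0]
    n_blocks = int(np.ceil(res["n_iter"][0] / 2))
    return DropoutFit(
        target_cell=target_cell,
        gene=gene,
        p=float(res["p"][0]),
        mu=float(res["mu"][0]),
        psi=float(res["psi"][0]),
        lambda_hat=lam,
        loglik_trace=trace[: max(n_blocks, 1)] if trace.size else trace,
        converged=bool(res["converged"][0]),
        counts=counts,
        depths=depths,
    )


def posterior_lambda(fit: DropoutFit, neighbor: int, observed_count: int, depth: float) -> float:
    """Posterior-mean rate for one neighbor given its observed count and depth."""
    lam = posterior_lambda_matrix(
        np.array([fit.p]), np.array([fit.mu]), np.array([fit.psi]),
        np.array([[observed_count]]), np.array([depth]),
    )
    return float(lam[0, 0])


def adjusted_predictor(lambda_hat) -> np.ndarray | float:
    """Map a per-read rate to the log-RPM scale: ln(1e6 * lambda + 0.1).

    1e6 * lambda is the rate expressed in reads-per-million, so a zero rate
    maps to ln(0.1), the same value an unexpressed gene takes in X.
    """
    lam = np.asarray(lambda_hat, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda_hat must be nonnegative")
    out = np.log(1e6 * lam + 0.1)
    return float(out) if out.ndim == 0 else out
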