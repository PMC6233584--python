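"""Simplex-constrained weight estimation by quadratic programming.

Given a target cell i and its candidate pool, the imputation weights
b_{i,l} minimize the sum of squared prediction errors

    sum_j ( X_{i,j} - sum_l X_{l,j} b_{i,l} )^2     over fitting genes j,

subject to b_{i,l} >= 0 and sum_l b_{i,l} = 1 (the probability simplex).
The equality constraint is handled by eliminating a designated reference
candidate r (the pool cell most correlated with the target, ties to the
lowest index): with W_j = X_{i,j} - X_{r,j} and Y_{l,j} = X_{l,j} - X_{r,j}
for l != r, the problem becomes

    min_beta  1/2 beta^T (sum_j Y_.j Y_.j^T) beta - (sum_j W_j Y_.j^T) beta
    s.t.      0 <= beta,  sum(beta) <= 1,

and b_r = 1 - sum(beta) >= 0 is recovered afterwards.  (beta <= 1 is
implied by nonnegativity plus the sum bound.)  A pool of exactly one
candidate has no reference to difference against; it is posed as the
scalar box-constrained QP in that candidate's weight directly.

The solver is an accelerated projected-gradient method (FISTA with
restarts) over {beta >= 0, sum(beta) <= 1} followed by an active-set
polish: any convex-QP method is acceptable here, and convergence is judged
by the natural-map residual ||beta - P(beta - grad)||_inf, which is zero
exactly at KKT points.

Estimated weights below t = 0.001 are hard-thresholded to zero and the
survivors renormalized to sum to one, yielding the final sparse
neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .neighbor_select import CandidatePool
from .preprocess import LogExprMatrix

logger = logging.getLogger(__name__)

WEIGHT_THRESHOLD = 0.001


class QPConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"QP solver did not reach tolerance in {iterations} iterations "
            f"(residual {residual:.3e})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass
class QPProblem:
    """min 1/2 b^T G b - a^T b over {b >= 0, sum(b) <= 1} (+ b <= 1 when scalar)."""

    G: np.ndarray
    a: np.ndarray
    pool: np.ndarray          # candidate cell indices, solver order
    ref_position: int | None  # position of the eliminated reference in `pool`; None for scalar form
    const: float = 0.0        # 1/2 sum_j W_j^2, so objective(beta) + const = 1/2 SSE

    @property
    def dim(self) -> int:
        return len(self.a)

    def objective(self, beta: np.ndarray) -> float:
        return float(0.5 * beta @ self.G @ beta - self.a @ beta)


@dataclass
class CellNeighborhood:
    """Final sparse neighborhood of one target cell."""

    target_cell: int
    neighbors: np.ndarray
    weights: np.ndarray
    objective: float = float("nan")
    raw_weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    raw_pool: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def prediction_sse(X: LogExprMatrix, target_cell: int, cells: np.ndarray, weights: np.ndarray,
                   genes: np.ndarray | None = None) -> float:
    """Sum of squared prediction errors of the weighted neighbor combination."""
    genes = X.fitting_genes if genes is None else np.asarray(genes)
    pred = weights @ X.X[np.asarray(cells)][:, genes]
    resid = X.X[target_cell, genes] - pred
    return float(resid @ resid)


def build_qp(
    X: LogExprMatrix,
    target_cell: int,
    pool: CandidatePool | np.ndarray,
    fitting_genes: np.ndarray | None = None,
) -> QPProblem:
    """Assemble the reference-eliminated (or scalar) QP for one target cell."""
    cells = pool.candidates if isinstance(pool, CandidatePool) else np.asarray(pool)
    if cells.size == 0:
        raise ValueError("empty candidate pool (the correlation fallback should have fired)")
    if target_cell in cells:
        raise ValueError("target cell found in its own candidate pool")
    genes = X.fitting_genes if fitting_genes is None else np.asarray(fitting_genes)
    if genes.size < cells.size:
        logger.warning(
            "fewer fitting genes (%d) than candidates (%d); QP may be rank-deficient",
            genes.size, cells.size,
        )

    x_t = X.X[target_cell, genes]
    P = X.X[cells][:, genes]  # pool x genes

    if cells.size == 1:
        Y = P[0]
        G = np.array([[Y @ Y]])
        a = np.array([x_t @ Y])
        return QPProblem(G=G, a=a, pool=cells.copy(), ref_position=None,
                         const=float(0.5 * x_t @ x_t))

    # reference = pool cell most correlated with the target (ties -> lowest index)
    xc = x_t - x_t.mean()
    Pc = P - P.mean(axis=1, keepdims=True)
    denom = np.sqrt((Pc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Pc @ xc) / denom
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    best = corr.max()
    # tie-break on the candidate *cell index*, not pool position
    tied = np.flatnonzero(corr == best) if np.isfinite(best) else np.arange(len(cells))
    ref_pos = int(tied[np.argmin(cells[tied])])

    x_ref = P[ref_pos]
    W = x_t - x_ref
    Y = np.delete(P, ref_pos, axis=0) - x_ref
    G = Y @ Y.T
    a = Y @ W
    order = np.concatenate([np.delete(cells, ref_pos), [cells[ref_pos]]])
    return QPProblem(G=G, a=a, pool=order, ref_position=len(order) - 1,
                     const=float(0.5 * W @ W))


def _project_capped_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {x >= 0, sum(x) <= 1}."""
    w = np.maximum(v, 0.0)
    if w.sum() <= 1.0:
        return w
    # project v onto the unit simplex {x >= 0, sum(x) = 1}
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / np.arange(1, len(v) + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _kkt_residual(problem: QPProblem, beta: np.ndarray) -> float:
    g = problem.G @ beta - problem.a
    return float(np.max(np.abs(beta - _project_capped_simplex(beta - g))))


def _polish_active_set(problem: QPProblem, beta: np.ndarray, tol: float) -> np.ndarray | None:
    """Solve the equality-constrained LS on the active set guessed from beta.

    Returns the exact stationary point if it is feasible and KKT-consistent,
    else None.
    """
    G, a = problem.G, problem.a
    free = beta > tol * 10
    if not free.any():
        free = np.zeros_like(free)
        free[int(np.argmax(a))] = True
    sum_active = beta.sum() > 1.0 - 1e-9
    idx = np.flatnonzero(free)
    Gf = G[np.ix_(idx, idx)]
    af = a[idx]
    try:
        if sum_active:
            k = len(idx)
            KKT = np.zeros((k + 1, k + 1))
            KKT[:k, :k] = Gf
            KKT[:k, k] = 1.0
            KKT[k, :k] = 1.0
            rhs = np.concatenate([af, [1.0]])
            sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
            bf = sol[:k]
        else:
            bf = np.linalg.lstsq(Gf, af, rcond=None)[0]
    except np.linalg.LinAlgError:
        return None
    cand = np.zeros_like(beta)
    cand[idx] = bf
    if cand.min() < -1e-12 or cand.sum() > 1.0 + 1e-9:
        return None
    cand = np.clip(cand, 0.0, None)
    s = cand.sum()
    if s > 1.0:
        cand /= s
    return cand


def solve_simplex_qp(problem: QPProblem, tol: float = 1e-8, max_iter: int = 10000) -> np.ndarray:
    """Solve the QP; return the full pool-length weight vector (sums to 1).

    The vector is aligned with ``problem.pool``; the eliminated reference
    weight b_r = 1 - sum(beta) occupies ``problem.ref_position``.  Raises
    :class:`QPConvergenceError` (carrying iteration count and residual) if
    the KKT residual cannot be brought below tolerance.
    """
    G, a = problem.G, problem.a
    p = problem.dim
    scale = max(1.0, float(np.max(np.abs(a))))
    tol_abs = tol * scale

    if p == 1 and problem.ref_position is None:
        # scalar box QP: analytic minimizer clipped to [0, 1]
        beta = np.clip(a[0] / G[0, 0], 0.0, 1.0) if G[0, 0] > 0 else (1.0 if a[0] > 0 else 0.0)
        return np.array([beta])

    L = float(np.linalg.eigvalsh(G)[-1]) if p > 1 else float(G[0, 0])
    L = max(L, 1e-12)
    beta = np.full(p, 1.0 / (p + 1))
    z = beta.copy()
    t_mom = 1.0
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        g = G @ z - a
        beta_new = _project_capped_simplex(z - g / L)
        if (beta_new - z) @ g > 0:  # restart on non-descent
            t_mom = 1.0
            z = beta
            g = G @ z - a
            beta_new = _project_capped_simplex(z - g / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = beta_new + ((t_mom - 1.0) / t_new) * (beta_new - beta)
        beta, t_mom = beta_new, t_new
        if it % 10 == 0 or it == max_iter:
            residual = _kkt_residual(problem, beta)
            if residual <= tol_abs:
                break
            polished = _polish_active_set(problem, beta, tol)
            if polished is not None:
                r2 = _kkt_residual(problem, polished)
                if r2 < residual:
                    beta, residual = polished, r2
                if residual <= tol_abs:
                    break
    if residual > tol_abs:
        raise QPConvergenceError(it, residual)

    full = np.empty(p + 1)
    full[:p] = beta
    full[p] = max(0.0, 1.0 - beta.sum())
    if problem.ref_position is None:  # scalar form: no reference cell
        return beta
    # numerical guard: clip tiny negatives, renormalize exactly to 1
    full = np.clip(full, 0.0, 1.0)
    s = full.sum()
    if s > 0:
        full /= s
    return full


def threshold_and_renormalize(
    weights: np.ndarray,
    pool: np.ndarray,
    t: float = WEIGHT_THRESHOLD,
    target_cell: int = -1,
) -> CellNeighborhood:
    """Hard-threshold raw weights at t and renormalize survivors to sum 1.

    If every weight falls below t, the single largest is kept at weight 1
    (with a warning): an empty neighborhood would leave the cell unimputable.
    """
    weights = np.asarray(weights, dtype=float)
    pool = np.asarray(pool)
    if weights.shape != pool.shape:
        raise ValueError("weights and pool must align")
    keep = weights >= t
    if not keep.any():
        logger.warning(
            "all %d weights below threshold %g for cell %d; keeping the largest",
            len(weights), t, target_cell,
        )
        keep = np.zeros_like(keep)
        keep[int(np.argmax(weights))] = True
        final = np.array([1.0])
    else:
        final = weights[keep] / weights[keep].sum()
    return CellNeighborhood(
        target_cell=target_cell,
        neighbors=pool[keep],
        weights=final,
        raw_weights=weights,
        raw_pool=pool,
    )


def estimate_weights(
    X: LogExprMatrix,
    target_cell: int,
    pool: CandidatePool | np.ndarray,
    t: float = WEIGHT_THRESHOLD,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> CellNeighborhood:
    """build_qp -> solve -> threshold, with the final SSE recorded."""
    problem = build_qp(X, target_cell, pool)
    raw = solve_simplex_qp(problem, tol=tol, max_iter=max_iter)
    hood = threshold_and_renormalize(raw, problem.pool, t=t, target_cell=target_cell)
    hood.objective = prediction_sse(X, target_cell, hood.neighbors, hood.weights)
    return hood
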