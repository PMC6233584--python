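import numpy as np
import pytest

from cellimp.preprocess import LogExprMatrix
from cellimp.qp_weights import (
    build_qp,
    estimate_weights,
    prediction_sse,
    solve_simplex_qp,
    threshold_and_renormalize,
)


def _as_X(mat):
    mat = np.asarray(mat, dtype=float)
    n, m = mat.shape
    return LogExprMatrix(
        X=mat, depths=np.ones(n), zero_mask=np.zeros_like(mat, dtype=bool),
        fitting_genes=np.arange(m),
        cell_ids=[f"c{i}" for i in range(n)], gene_ids=[f"g{j}" for j in range(m)],
    )


def _simplex_grid(d, step):
    """All weight vectors on the d-simplex with the given resolution."""
    n = int(round(1 / step))
    if d == 1:
        return np.array([[1.0]])
    axes = np.meshgrid(*[np.arange(n + 1)] * (d - 1), indexing="ij")
    flat = np.stack([a.ravel() for a in axes], axis=1)
    keep = flat.sum(axis=1) <= n
    pts = flat[keep]
    last = n - pts.sum(axis=1, keepdims=True)
    return np.hstack([pts, last]) / n


def _grid_best_sse(X, target, pool, step=0.005):
    P = X.X[np.asarray(pool)]
    W = X.X[target]
    pts = _simplex_grid(len(pool), step)
    resid = pts @ P - W[None, :]
    return np.min((resid**2).sum(axis=1))


def test_gram_is_symmetric_psd():
    rng = np.random.default_rng(0)
    X = _as_X(rng.normal(size=(6, 30)))
    prob = build_qp(X, 0, np.array([1, 2, 3, 4]))
    np.testing.assert_allclose(prob.G, prob.G.T)
    assert np.linalg.eigvalsh(prob.G).min() > -1e-10


def test_objective_equals_sse_up_to_constant():
    rng = np.random.default_rng(1)
    X = _as_X(rng.normal(size=(5, 40)))
    pool = np.array([1, 2, 3, 4])
    prob = build_qp(X, 0, pool)
    for _ in range(5):
        beta = rng.dirichlet(np.ones(prob.dim + 1))[: prob.dim]
        full = np.append(beta, 1 - beta.sum())
        sse = prediction_sse(X, 0, prob.pool, full)
        np.testing.assert_allclose(prob.objective(beta) + prob.const, 0.5 * sse, rtol=1e-10)


def test_single_candidate_scalar_qp():
    X = _as_X(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]))
    prob = build_qp(X, 0, np.array([1]))
    assert prob.dim == 1 and prob.ref_position is None
    raw = solve_simplex_qp(prob)
    # analytic: argmin |x0 - b*x1|^2 = <x0,x1>/<x1,x1> = 0.5, inside [0, 1]
    np.testing.assert_allclose(raw, [0.5], atol=1e-10)


def test_duplicate_candidate_takes_all_weight():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(5, 50))
    base[1] = base[0]  # candidate 1 duplicates the target
    X = _as_X(base)
    hood = estimate_weights(X, 0, np.array([1, 2, 3, 4]))
    w = dict(zip(hood.neighbors.tolist(), hood.weights))
    assert w.get(1, 0.0) == pytest.approx(1.0, abs=1e-6)


def test_exact_convex_combination_recovered():
    rng = np.random.default_rng(3)
    A, B = rng.normal(size=50), rng.normal(size=50)
    X = _as_X(np.vstack([0.3 * A + 0.7 * B, A, B]))
    hood = estimate_weights(X, 0, np.array([1, 2]))
    w = dict(zip(hood.neighbors.tolist(), hood.weights))
    assert w[1] == pytest.approx(0.3, abs=1e-6)
    assert w[2] == pytest.approx(0.7, abs=1e-6)


@pytest.mark.parametrize("seed", range(6))
def test_solver_matches_simplex_grid_search(seed):
    rng = np.random.default_rng(seed)
    d = rng.integers(2, 5)
    X = _as_X(rng.normal(size=(d + 1, 30)))
    pool = np.arange(1, d + 1)
    prob = build_qp(X, 0, pool)
    raw = solve_simplex_qp(prob)
    sse = prediction_sse(X, 0, prob.pool, raw)
    best = _grid_best_sse(X, 0, pool, step=0.005)
    assert sse <= best + 1e-5


def test_solver_weights_feasible():
    rng = np.random.default_rng(9)
    X = _as_X(rng.normal(size=(8, 60)))
    prob = build_qp(X, 0, np.arange(1, 8))
    raw = solve_simplex_qp(prob)
    assert raw.min() >= -1e-12 and raw.max() <= 1 + 1e-12
    assert raw.sum() == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("weights,pool,expect", [
    ([0.9995, 0.0005], [0, 1], {0: 1.0}),
    ([0.5, 0.5], [0, 1], {0: 0.5, 1: 0.5}),
    ([0.6, 0.3995, 0.0005], [0, 1, 2], {0: 0.6 / 0.9995, 1: 0.3995 / 0.9995}),
])
def test_threshold_worked_vectors(weights, pool, expect):
    hood = threshold_and_renormalize(np.array(weights), np.array(pool), t=0.001)
    got = dict(zip(hood.neighbors.tolist(), hood.weights))
    assert set(got) == set(expect)
    for k, v in expect.items():
        assert got[k] == pytest.approx(v, abs=1e-12)
    assert hood.weights.sum() == pytest.approx(1.0, abs=1e-8)


def test_threshold_all_below_keeps_largest(caplog):
    hood = threshold_and_renormalize(np.array([4e-4, 5e-4, 1e-4]), np.arange(3), t=0.001)
    assert hood.neighbors.tolist() == [1]
    assert hood.weights.tolist() == [1.0]


def test_final_weights_within_threshold_bounds():
    rng = np.random.default_rng(4)
    X = _as_X(rng.normal(size=(10, 80)))
    hood = estimate_weights(X, 0, np.arange(1, 10))
    assert np.all(hood.weights >= 0.001 / hood.raw_weights[hood.raw_weights >= 0.001].sum() - 1e-12)
    assert hood.weights.sum() == pytest.approx(1.0, abs=1e-8)
    assert 0 not in hood.neighbors


def test_thresholding_cannot_improve_objective():
    rng = np.random.default_rng(6)
    X = _as_X(rng.normal(size=(6, 40)))
    pool = np.arange(1, 6)
    prob = build_qp(X, 0, pool)
    raw = solve_simplex_qp(prob)
    hood = threshold_and_renormalize(raw, prob.pool, t=0.05, target_cell=0)
    sse_raw = prediction_sse(X, 0, prob.pool, raw)
    sse_final = prediction_sse(X, 0, hood.neighbors, hood.weights)
    assert sse_final >= sse_raw - 1e-10
    assert sse_raw >= 0 and sse_final >= 0


def test_neighborhoods_are_asymmetric():
    # cell0 is the midpoint of cells 1 and 2; cell1 has an exact duplicate (cell3).
    rng = np.random.default_rng(8)
    c1, c2 = rng.normal(size=50), rng.normal(size=50)
    c0 = 0.5 * (c1 + c2)
    X = _as_X(np.vstack([c0, c1, c2, c1.copy()]))
    hood0 = estimate_weights(X, 0, np.array([1, 2, 3]))
    hood1 = estimate_weights(X, 1, np.array([0, 2, 3]))
    assert 1 in hood0.neighbors or 3 in hood0.neighbors
    assert 3 in hood1.neighbors          # the duplicate dominates
    assert 0 not in hood1.neighbors      # asymmetry: 1 in N(0) but 0 not in N(1)


# ---- property tests -------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=1, max_size=12))
def test_capped_simplex_projection_properties(vals):
    """The projection onto {x >= 0, sum(x) <= 1} is feasible and idempotent."""
    from cellimp.qp_weights import _project_capped_simplex

    v = np.array(vals)
    p = _project_capped_simplex(v)
    assert p.min() >= 0
    assert p.sum() <= 1 + 1e-9
    np.testing.assert_allclose(_project_capped_simplex(p), p, atol=1e-12)
    # projection is the closest feasible point: no feasible vertex is closer
    for k in range(len(v)):
        e = np.zeros_like(v)
        e[k] = 1.0
        assert np.sum((p - v) ** 2) <= np.sum((e - v) ** 2) + 1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=10),
       st.floats(1e-6, 0.2))
def test_threshold_renormalize_invariants(raw, t):
    """Survivors sum to one; no survivor falls below the threshold."""
    w = np.array(raw)
    if w.sum() == 0:
        w[0] = 1.0
    w = w / w.sum()
    hood = threshold_and_renormalize(w, np.arange(len(w)), t=t)
    assert hood.weights.sum() == pytest.approx(1.0, abs=1e-8)
    assert len(hood.neighbors) >= 1
    assert np.all(np.isin(hood.neighbors, np.arange(len(w))))
    if (w >= t).any():
        assert np.all(w[np.searchsorted(np.arange(len(w)), hood.neighbors)] >= t)
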