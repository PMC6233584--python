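"""Pre-selection of candidate neighbor cells via penalized regression.

For a target cell i, its log expression over a random subset of fitting
genes is regressed on the expression of all other cells — genes play the
role of observations, cells of predictors.  An L1 (lasso) or L1+L2
(elastic-net, mixing 0.5) penalty with k-fold cross-validation over genes
picks the penalty strength; cells with a non-zero coefficient (either
sign) at the selected penalty form the candidate pool handed to the
quadratic-programming weight-estimation stage.

All targets share the same design matrix (columns = cells), so the
per-fold centered Gram matrices are computed once per run and reused for
every target cell (`PreselectEngine`); removing the target's row/column
from a precomputed Gram is far cheaper than re-forming it.  The fold
assignment over genes is drawn once from the run seed and shared across
cells, which also makes penalty selection comparable between cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path

from ._lars_kernel import lars_lasso_gram

from .preprocess import LogExprMatrix

logger = logging.getLogger(__name__)

ENET_L1_RATIO = 0.5  # mixing for method="l1+l2"


@dataclass
class CandidatePool:
    """Candidate predictive cells for one target cell."""

    target_cell: int
    candidates: np.ndarray
    method: str = "l1"
    penalty: float = float("nan")
    gene_subset: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def size(self) -> int:
        return len(self.candidates)


def sample_gene_subset(fitting_genes: np.ndarray, size: int = 5000, seed: int = 0) -> np.ndarray:
    """Uniform sample without replacement of min(size, |fitting_genes|) genes.

    Deterministic given the seed; returned sorted for reproducible downstream
    indexing.
    """
    fitting_genes = np.asarray(fitting_genes)
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if fitting_genes.size == 0:
        raise ValueError("empty fitting gene set")
    k = min(size, fitting_genes.size)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(fitting_genes, size=k, replace=False))


class PreselectEngine:
    """Shared cross-validation machinery for pre-selecting candidates.

    Precomputes, per CV fold, the column means and Gram matrix of the
    gene-subset design (genes x cells), then answers per-target queries by
    deleting the target's row/column from each Gram.
    """

    def __init__(
        self,
        X: LogExprMatrix,
        gene_subset: np.ndarray,
        method: str = "l1",
        folds: int = 10,
        seed: int = 0,
        n_alphas: int = 30,
        eps: float = 1e-3,
        max_path_steps: int = 300,
    ) -> None:
        if method not in ("l1", "l1+l2"):
            raise ValueError(f"method must be 'l1' or 'l1+l2', got {method!r}")
        if X.n_cells < 3:
            raise ValueError("need at least 3 cells for pre-selection")
        gene_subset = np.asarray(gene_subset)
        if gene_subset.size < folds:
            raise ValueError(
                f"gene subset ({gene_subset.size}) smaller than fold count ({folds})"
            )
        self.method = method
        self.folds = folds
        self.seed = seed
        self.n_alphas = n_alphas
        self.eps = eps
        # LARS step cap: the CV minimum sits at moderate pool sizes, far
        # shallower than the full path among collinear cells
        self.max_path_steps = max_path_steps
        self.gene_subset = gene_subset
        self.l1_ratio = 1.0 if method == "l1" else ENET_L1_RATIO

        D = np.asfortranarray(X.X[:, gene_subset].T)  # genes x cells
        self.D = D
        n_genes = D.shape[0]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_genes)
        self.fold_val = np.array_split(perm, folds)

        # full-data centered design and Gram (for the final fit)
        self.mean_all = D.mean(axis=0)
        self.C_all = np.asfortranarray(D - self.mean_all)
        self.K_all = self.C_all.T @ self.C_all

        self.fold_train: list[np.ndarray] = []
        self.fold_mean: list[np.ndarray] = []
        self.fold_C: list[np.ndarray] = []
        self.fold_K: list[np.ndarray] = []
        for val in self.fold_val:
            mask = np.ones(n_genes, dtype=bool)
            mask[val] = False
            tr = np.flatnonzero(mask)
            Ctr = D[tr]
            mu = Ctr.mean(axis=0)
            Ctr = np.asfortranarray(Ctr - mu)
            self.fold_train.append(tr)
            self.fold_mean.append(mu)
            self.fold_C.append(Ctr)
            self.fold_K.append(Ctr.T @ Ctr)

    def _alpha_grid(self, Xy: np.ndarray, n_samples: int) -> np.ndarray:
        alpha_max = np.max(np.abs(Xy)) / (n_samples * self.l1_ratio)
        if alpha_max <= 0 or not np.isfinite(alpha_max):
            return np.array([])
        return np.logspace(np.log10(alpha_max), np.log10(alpha_max * self.eps), self.n_alphas)

    def preselect(self, target_cell: int) -> CandidatePool:
        i = target_cell
        n_cells = self.D.shape[1]
        others = np.delete(np.arange(n_cells), i)
        y_all = self.D[:, i]
        if np.std(y_all) == 0:
            logger.warning("cell %d has constant expression over the gene subset; no candidates", i)
            return self._empty_pool(i)

        alphas = self._alpha_grid(np.delete(self.K_all[:, i], i), self.D.shape[0])
        if alphas.size == 0:
            return self._empty_pool(i)

        if self.l1_ratio == 1.0:
            return self._preselect_lars(i, others, alphas)
        return self._preselect_cd(i, others, alphas)

    @staticmethod
    def _interp_path(bp_alphas: np.ndarray, coefs: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """Interpolate a LARS-lasso path (exactly piecewise linear in alpha)
        onto a fixed alpha grid.  bp_alphas decreasing; returns (p, len(grid))."""
        out = np.zeros((coefs.shape[0], len(grid)))
        for g_idx, g in enumerate(grid):
            if g >= bp_alphas[0]:
                continue  # above the first breakpoint: all-zero solution
            if g <= bp_alphas[-1]:
                out[:, g_idx] = coefs[:, -1]
                continue
            j = np.searchsorted(-bp_alphas, -g) - 1  # bp[j] >= g > bp[j+1]
            span = bp_alphas[j] - bp_alphas[j + 1]
            t = 0.0 if span == 0 else (bp_alphas[j] - g) / span
            out[:, g_idx] = coefs[:, j] * (1 - t) + coefs[:, j + 1] * t
        return out

    def _preselect_lars(self, i: int, others: np.ndarray, alphas: np.ndarray) -> CandidatePool:
        """Lasso pre-selection via the exact LARS path on precomputed Grams.

        The path is expensive deep down (hundreds of LARS steps among
        collinear cells), so the CV search is staged: evaluate the top of
        the grid first and only extend deeper while the CV minimum sits at
        the boundary of what has been computed.
        """
        n_grid = len(alphas)
        fold_data = []
        for f in range(self.folds):
            fold_data.append((
                np.delete(np.delete(self.fold_K[f], i, axis=0), i, axis=1),
                np.delete(self.fold_K[f][:, i], i),
                len(self.fold_train[f]),
                np.delete(self.fold_mean[f], i),
                self.fold_mean[f][i],
                self.D[self.fold_val[f]][:, others],
                self.D[self.fold_val[f]][:, [i]],
            ))
        stop = max(2, int(np.ceil(n_grid / 3)))
        while True:
            grid = alphas[:stop]
            mse = np.zeros((self.folds, len(grid)))
            for f, (K, Xy, n_tr, mu, mu_y, V, yv) in enumerate(fold_data):
                bp, coefs, _ = lars_lasso_gram(K, Xy, n_tr, float(grid[-1]),
                                               self.max_path_steps)
                grid_coefs = self._interp_path(bp, coefs.T, grid)
                pred = V @ grid_coefs + (mu_y - mu @ grid_coefs)
                mse[f] = np.mean((pred - yv) ** 2, axis=0)
            best = int(np.argmin(mse.mean(axis=0)))
            if best < len(grid) - 2 or stop >= n_grid:
                break
            stop = min(n_grid, stop + max(2, int(np.ceil(n_grid / 3))))
        alpha = float(alphas[best])

        K = np.delete(np.delete(self.K_all, i, axis=0), i, axis=1)
        Xy = np.delete(self.K_all[:, i], i)
        bp, coefs, _ = lars_lasso_gram(K, Xy, self.D.shape[0], alpha, self.max_path_steps)
        final = self._interp_path(bp, coefs.T, np.array([alpha]))[:, 0]
        nz = np.flatnonzero(final != 0)
        return CandidatePool(
            target_cell=i,
            candidates=others[nz],
            method=self.method,
            penalty=alpha,
            gene_subset=self.gene_subset,
        )

    def _preselect_cd(self, i: int, others: np.ndarray, alphas: np.ndarray) -> CandidatePool:
        # Per-fold warm-started path computed in chunks of alphas; the walk
        # down the path stops once the CV curve has clearly passed its
        # minimum (tiny penalties on collinear cell designs are both slow
        # and never selected).
        p = len(others)
        fold_state = []
        for f in range(self.folds):
            fold_state.append({
                "K": np.delete(np.delete(self.fold_K[f], i, axis=0), i, axis=1),
                "Xy": np.delete(self.fold_K[f][:, i], i),
                "Ctr": np.delete(self.fold_C[f], i, axis=1),
                "y": self.fold_C[f][:, i],
                "mu": np.delete(self.fold_mean[f], i),
                "mu_y": self.fold_mean[f][i],
                "V": self.D[self.fold_val[f]][:, others],
                "yv": self.D[self.fold_val[f]][:, [i]],
                "coef": np.zeros(p),
            })
        chunk = 8
        mse_cols: list[np.ndarray] = []
        n_done = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            while n_done < len(alphas):
                sl = slice(n_done, min(n_done + chunk, len(alphas)))
                for st in fold_state:
                    _, coefs, _ = enet_path(
                        st["Ctr"], st["y"], l1_ratio=self.l1_ratio, alphas=alphas[sl],
                        precompute=st["K"], Xy=st["Xy"], coef_init=st["coef"].copy(),
                        check_input=False, max_iter=300, tol=1e-3,
                    )
                    st["coef"] = coefs[:, -1]
                    pred = st["V"] @ coefs + (st["mu_y"] - st["mu"] @ coefs)
                    st["mse_chunk"] = np.mean((pred - st["yv"]) ** 2, axis=0)
                mse_cols.append(np.mean([st["mse_chunk"] for st in fold_state], axis=0))
                n_done = sl.stop
                curve = np.concatenate(mse_cols)
                if np.argmin(curve) < len(curve) - chunk:
                    break

            curve = np.concatenate(mse_cols)
            best = int(np.argmin(curve))
            alpha = float(alphas[best])

            K = np.delete(np.delete(self.K_all, i, axis=0), i, axis=1)
            Xy = np.delete(self.K_all[:, i], i)
            C = np.delete(self.C_all, i, axis=1)
            _, coefs, _ = enet_path(
                C, self.C_all[:, i], l1_ratio=self.l1_ratio, alphas=alphas[: best + 1],
                precompute=K, Xy=Xy, check_input=False, max_iter=1000,
            )
        nz = np.flatnonzero(coefs[:, -1] != 0)
        return CandidatePool(
            target_cell=i,
            candidates=others[nz],
            method=self.method,
            penalty=alpha,
            gene_subset=self.gene_subset,
        )

    def _empty_pool(self, i: int) -> CandidatePool:
        return CandidatePool(
            target_cell=i,
            candidates=np.empty(0, dtype=int),
            method=self.method,
            gene_subset=self.gene_subset,
        )


def preselect_candidates(
    X: LogExprMatrix,
    target_cell: int,
    gene_subset: np.ndarray,
    method: str = "l1",
    folds: int = 10,
    seed: int = 0,
) -> CandidatePool:
    """Single-target convenience wrapper around :class:`PreselectEngine`.

    Pipelines that visit every cell should build one engine and reuse it;
    this wrapper rebuilds the fold Grams on each call.
    """
    return PreselectEngine(X, gene_subset, method=method, folds=folds, seed=seed).preselect(target_cell)


def fallback_candidates(X: LogExprMatrix, target_cell: int, k: int = 50) -> CandidatePool:
    """Correlation-ranked fallback used when the penalized selection is empty.

    Returns the k cells with highest Pearson correlation to the target over
    the fitting genes (all other cells when k >= n-1); ties break toward the
    lower cell index.
    """
    genes = X.fitting_genes
    M = X.X[:, genes]
    y = M[target_cell]
    yc = y - y.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt((Mc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Mc @ yc) / denom
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    corr[target_cell] = -np.inf
    order = np.lexsort((np.arange(X.n_cells), -corr))
    order = order[order != target_cell]
    return CandidatePool(
        target_cell=target_cell,
        candidates=order[: min(k, X.n_cells - 1)],
        method="correlation-fallback",
    )
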