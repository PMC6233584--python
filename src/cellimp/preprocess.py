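"""Normalization and filtering of count matrices.

Counts are normalized to reads-per-million, R_{i,j} = C_{i,j} / N_i * 1e6
(N_i the cell's total depth), then log-transformed with a pseudo-value,
X_{i,j} = ln(R_{i,j} + 0.1).  Natural log throughout; the constant
ln(0.1) ~ -2.302585 is the value every zero count maps to.

Two count-level filters mirror common practice: genes must be expressed
(count > 0) in at least a fraction of cells (inclusive >=), and cells must
exceed a minimum library size (strict >).  A third, stricter gene set — the
"fitting genes", zero-count fraction strictly below a threshold — is used
for weight estimation so that missing values do not distort the regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import CountMatrix, MatrixValidationError

logger = logging.getLogger(__name__)

LOG_ZERO = float(np.log(0.1))


@dataclass
class LogExprMatrix:
    """Log-RPM expression with bookkeeping for imputation.

    X is cells x genes; ``zero_mask`` marks entries whose count was 0 (all of
    which equal ln 0.1 in X); ``fitting_genes`` indexes the genes eligible
    for weight estimation.
    """

    X: np.ndarray
    depths: np.ndarray
    zero_mask: np.ndarray
    fitting_genes: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


def compute_rpm(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Reads-per-million normalization.

    Returns (rpm, depths).  Every retained cell must have positive depth;
    zero-depth cells are an error (filter them first), never silently dropped.
    """
    depths = counts.depths
    if np.any(depths == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(depths == 0)]
        raise MatrixValidationError(
            f"cells with zero total depth (filter before normalizing): {bad[:10]}"
        )
    rpm = counts.counts / depths[:, None] * 1e6
    return rpm, depths


def log_transform(rpm: np.ndarray) -> np.ndarray:
    """X = ln(R + 0.1).  Strictly monotone, hence order-preserving."""
    rpm = np.asarray(rpm, dtype=float)
    if np.any(rpm < 0):
        raise MatrixValidationError("negative RPM value passed to log_transform")
    return np.log(rpm + 0.1)


def filter_genes_by_expression(counts: CountMatrix, min_expressed_fraction: float = 0.10) -> CountMatrix:
    """Retain genes expressed (count > 0) in >= min_expressed_fraction of cells.

    The boundary is inclusive: a gene expressed in exactly the threshold
    fraction of cells is kept.  Gene order is preserved.
    """
    if not 0 < min_expressed_fraction <= 1:
        raise MatrixValidationError(
            f"min_expressed_fraction must be in (0, 1], got {min_expressed_fraction}"
        )
    frac = (counts.counts > 0).mean(axis=0)
    keep = np.flatnonzero(frac >= min_expressed_fraction)
    return counts.subset_genes(keep)


def filter_cells_by_library(counts: CountMatrix, min_total: int = 0) -> CountMatrix:
    """Retain cells with library size strictly greater than min_total."""
    if min_total < 0:
        raise MatrixValidationError(f"min_total must be >= 0, got {min_total}")
    keep = np.flatnonzero(counts.depths > min_total)
    return counts.subset_cells(keep)


def select_fitting_genes(
    zero_mask: np.ndarray,
    max_zero_fraction: float = 0.10,
    min_genes: int = 500,
) -> np.ndarray:
    """Genes whose zero-count fraction across cells is strictly below the threshold.

    If fewer than ``min_genes`` pass, the threshold is relaxed in steps of
    0.05 (with a logged warning) until the floor is met or the threshold
    reaches 1; very sparse data would otherwise leave nothing to fit on.
    """
    if not 0 < max_zero_fraction <= 1:
        raise MatrixValidationError(
            f"max_zero_fraction must be in (0, 1], got {max_zero_fraction}"
        )
    zero_frac = zero_mask.mean(axis=0)
    thr = max_zero_fraction
    genes = np.flatnonzero(zero_frac < thr)
    floor = min(min_genes, zero_mask.shape[1])
    while genes.size < floor and thr < 1.0:
        thr = min(1.0, thr + 0.05)
        genes = np.flatnonzero(zero_frac < thr)
        logger.warning(
            "only %d genes below zero-rate threshold; relaxed to %.2f (%d genes)",
            genes.size, thr, genes.size,
        )
    if genes.size == 0:
        raise MatrixValidationError(
            "no gene passes the fitting zero-rate threshold even after relaxation; "
            "relax max_zero_fraction or reconsider the input"
        )
    return genes


def normalize(
    counts: CountMatrix,
    fitting_zero_rate: float = 0.10,
    min_fitting_genes: int = 500,
) -> LogExprMatrix:
    """Full normalization: RPM -> log, plus zero mask and fitting-gene set."""
    rpm, depths = compute_rpm(counts)
    X = log_transform(rpm)
    zero_mask = counts.counts == 0
    fitting = select_fitting_genes(zero_mask, fitting_zero_rate, min_fitting_genes)
    return LogExprMatrix(
        X=X,
        depths=depths,
        zero_mask=zero_mask,
        fitting_genes=fitting,
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
    )
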