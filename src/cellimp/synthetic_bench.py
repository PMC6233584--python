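"""Synthetic scRNA-seq data and the evaluation experiments run on it.

The generator emulates the statistical structure the imputation model
assumes: distinct cell subpopulations with shared within-group expression
profiles, log-uniform library-size variation, gamma-Poisson (negative
binomial) over-dispersion, and expression-dependent dropout injected with
a decreasing logistic function of the underlying mean.  Truth and dropout
mask are recorded so imputed values can be scored against known answers.

Two perturbation experiments mirror standard imputation benchmarks:

* masking — a fixed percentage of non-zero entries is set to zero and the
  imputed values are correlated with the masked truth;
* two-step down-sampling — per-gene multinomial thinning to a retained
  fraction of reads (preserving each cell's expected share), followed by
  extra dropout events on the surviving non-zeros, either at a fixed rate
  or with per-subpopulation logistic rates fitted to the original data.
  Every zero in the result carries a provenance label.

The metric suite: per-cell-median (or pooled) Pearson correlation, squared
and L1 losses, per-gene coefficient-of-variation pairs before/after
imputation, top-k Jaccard overlap, and a split-half reproducibility
harness that accepts any per-gene ranking function (a Wilcoxon rank-sum
ranking is built in as a stand-in for external DE engines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

from .matrix_io import CountMatrix
from .preprocess import LOG_ZERO, log_transform

logger = logging.getLogger(__name__)

PROVENANCE_NONZERO = 0
PROVENANCE_ORIGINAL_ZERO = 1
PROVENANCE_DOWNSAMPLING_ZERO = 2
PROVENANCE_DROPOUT_ZERO = 3
PROVENANCE_LABELS = {
    PROVENANCE_NONZERO: "nonzero",
    PROVENANCE_ORIGINAL_ZERO: "original_zero",
    PROVENANCE_DOWNSAMPLING_ZERO: "downsampling_zero",
    PROVENANCE_DROPOUT_ZERO: "dropout_zero",
}

DOWNSAMPLE_RATES = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)
FIXED_DROPOUT_RATE = 0.8
MASK_PERCENTAGES = (0.02, 0.05, 0.10)
JACCARD_KS = (100, 200, 500, 1000)


@dataclass
class SyntheticDataset:
    """Counts with known truth, subpopulation labels, and dropout mask."""

    counts: CountMatrix
    truth_counts: CountMatrix
    cell_labels: np.ndarray
    dropout_mask: np.ndarray
    params: dict = field(default_factory=dict)


@dataclass
class DownsampleResult:
    """Two-step down-sampled matrix with per-entry zero provenance."""

    downsampled: CountMatrix
    zero_provenance: np.ndarray  # int codes, see PROVENANCE_LABELS
    retain_fraction: float
    dropout_model: str


@dataclass
class MaskedEntries:
    """Index and true values of entries masked to zero."""

    rows: np.ndarray
    cols: np.ndarray
    true_counts: np.ndarray


# ---------------------------------------------------------------------------
# generation

def simulate_counts(
    n_cells: int = 1000,
    n_genes: int = 2000,
    n_subpops: int = 3,
    depth_range: tuple[float, float] = (5e4, 2e5),
    logmean_spread: float = 1.0,
    dispersion: float = 0.3,
    dropout_logistic_params: tuple[float, float] | None = (1.0, -1.5),
    de_fraction: float = 0.3,
    base_log_sd: float = 1.5,
    silent_fraction: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a multi-subpopulation count matrix with known dropouts.

    Gene relative abundances are log-normal; each subpopulation shifts a
    ``de_fraction`` of genes by Normal(0, logmean_spread) to create
    differential structure, and additionally silences a ``silent_fraction``
    of genes (rate scaled by 1e-3 — true absence of expression in that
    subpopulation, the biological-zero regime as opposed to dropout).
    Counts are gamma-Poisson with the given dispersion
    (variance = mean + dispersion * mean^2) scaled by a log-uniform
    per-cell depth.  Dropout is injected per entry with probability
    sigmoid(a + b * ln(mean + 0.1)) for ``dropout_logistic_params =
    (a, b)`` (b < 0 makes it decreasing in the mean); ``None`` disables
    dropout.  Fully deterministic given the seed.
    """
    if min(n_cells, n_genes, n_subpops) < 1:
        raise ValueError("n_cells, n_genes, n_subpops must all be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not 0 < depth_range[0] <= depth_range[1]:
        raise ValueError("depth_range must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)

    if not 0 <= silent_fraction < 1:
        raise ValueError("silent_fraction must be in [0, 1)")
    base = rng.normal(0.0, base_log_sd, size=n_genes)
    shifts = np.zeros((n_subpops, n_genes))
    silenced = np.zeros((n_subpops, n_genes), dtype=bool)
    for k in range(n_subpops):
        de = rng.random(n_genes) < de_fraction
        shifts[k, de] = rng.normal(0.0, logmean_spread, size=de.sum())
        if silent_fraction > 0:
            silenced[k] = rng.random(n_genes) < silent_fraction
            shifts[k, silenced[k]] = np.log(1e-3)
    rates = np.exp(base[None, :] + shifts)
    props = rates / rates.sum(axis=1, keepdims=True)          # subpop x gene

    labels = np.arange(n_cells) % n_subpops
    rng.shuffle(labels)
    depths = np.exp(rng.uniform(np.log(depth_range[0]), np.log(depth_range[1]), n_cells))

    mean = depths[:, None] * props[labels]                    # cell x gene
    if dispersion > 0:
        gamma = rng.gamma(1.0 / dispersion, dispersion, size=mean.shape)
        truth = rng.poisson(mean * gamma)
    else:
        truth = rng.poisson(mean)

    if dropout_logistic_params is None:
        pdrop = np.zeros_like(mean)
    else:
        a, b = dropout_logistic_params
        logit = a + b * np.log(mean + 0.1)
        with np.errstate(over="ignore"):
            pdrop = 1.0 / (1.0 + np.exp(-logit))
    events = rng.random(mean.shape) < pdrop
    dropout_mask = events & (truth > 0)
    observed = np.where(dropout_mask, 0, truth)

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    gene_ids = [f"gene{j:05d}" for j in range(n_genes)]
    return SyntheticDataset(
        counts=CountMatrix(observed, cell_ids, gene_ids),
        truth_counts=CountMatrix(truth, list(cell_ids), list(gene_ids)),
        cell_labels=labels,
        dropout_mask=dropout_mask,
        params=dict(
            n_cells=n_cells, n_genes=n_genes, n_subpops=n_subpops,
            depth_range=tuple(depth_range), logmean_spread=logmean_spread,
            dispersion=dispersion, dropout_logistic_params=dropout_logistic_params,
            de_fraction=de_fraction, base_log_sd=base_log_sd,
            silent_fraction=silent_fraction, seed=seed,
            subpop_proportions=props, silenced=silenced,
        ),
    )


# ---------------------------------------------------------------------------
# masking and down-sampling

def mask_nonzero(counts: CountMatrix, pct: float, seed: int = 0) -> tuple[CountMatrix, MaskedEntries]:
    """Mask a uniform sample of round(pct * #nonzero) non-zero entries to zero."""
    if not 0 < pct < 1:
        raise ValueError(f"pct must be in (0, 1), got {pct}")
    rows, cols = np.nonzero(counts.counts)
    n_mask = int(round(pct * len(rows)))
    if n_mask < 1:
        raise ValueError(
            f"pct={pct} selects zero of {len(rows)} non-zero entries; need at least one"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n_mask, replace=False)
    r, c = rows[pick], cols[pick]
    vals = counts.counts[r, c].copy()
    masked = counts.counts.copy()
    masked[r, c] = 0
    return (
        CountMatrix(masked, list(counts.cell_ids), list(counts.gene_ids)),
        MaskedEntries(rows=r, cols=c, true_counts=vals),
    )


def multinomial_downsample(counts: CountMatrix, retain_fraction: float, seed: int = 0) -> CountMatrix:
    """Per-gene multinomial thinning to a retained fraction of reads.

    For each gene, round(retain * total) reads are re-drawn across cells
    with probabilities equal to each cell's share of that gene's reads, so
    the expected expression proportion per cell is unchanged.  Genes with
    zero total stay all-zero.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError(f"retain_fraction must be in (0, 1], got {retain_fraction}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts.counts)
    for j in range(counts.n_genes):
        col = counts.counts[:, j]
        total = int(col.sum())
        if total == 0:
            continue
        trials = int(round(retain_fraction * total))
        if trials == 0:
            continue
        out[:, j] = rng.multinomial(trials, col / total)
    return CountMatrix(out, list(counts.cell_ids), list(counts.gene_ids))


def fit_logistic_dropout(counts: CountMatrix, cell_labels: np.ndarray) -> dict:
    """Fit, per subpopulation, zero-fraction ~ logistic(a + b * nonzero mean).

    For each subpopulation and gene, the outcome is the fraction of cells
    with a zero count and the explanatory variable is the mean of the
    non-zero values; the fit is fractional-response maximum likelihood
    (binomial GLM with proportion outcomes).  Returns
    {label: (intercept, slope)}.
    """
    cell_labels = np.asarray(cell_labels)
    coeffs: dict = {}
    for lab in np.unique(cell_labels):
        sub = counts.counts[cell_labels == lab]
        if sub.shape[0] < 2:
            raise ValueError(f"subpopulation {lab!r} has fewer than 2 cells")
        zero_frac = (sub == 0).mean(axis=0)
        with np.errstate(invalid="ignore"):
            nz_mean = np.where(
                (sub > 0).any(axis=0),
                sub.sum(axis=0) / np.maximum((sub > 0).sum(axis=0), 1),
                np.nan,
            )
        usable = np.isfinite(nz_mean)
        if usable.sum() < 10:
            raise ValueError(
                f"subpopulation {lab!r}: fewer than 10 genes with a non-zero mean"
            )
        if np.all(zero_frac[usable] == 0) or np.all(zero_frac[usable] == 1):
            raise ValueError(
                f"subpopulation {lab!r} is degenerate (all-zero or all-nonzero outcomes)"
            )
        exog = sm.add_constant(nz_mean[usable])
        model = sm.GLM(zero_frac[usable], exog, family=sm.families.Binomial())
        res = model.fit()
        coeffs[lab] = (float(res.params[0]), float(res.params[1]))
    return coeffs


@dataclass
class FixedDropout:
    rate: float

    def probabilities(self, values: np.ndarray, rows: np.ndarray) -> np.ndarray:
        return np.full(values.shape, self.rate)


@dataclass
class LogisticDropout:
    coeffs: dict            # label -> (intercept, slope)
    labels: np.ndarray      # per-cell subpopulation labels

    def probabilities(self, values: np.ndarray, rows: np.ndarray) -> np.ndarray:
        labs = np.asarray(self.labels)[rows]
        a = np.array([self.coeffs[l][0] for l in labs])
        b = np.array([self.coeffs[l][1] for l in labs])
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-(a + b * values)))


def apply_dropout(counts: CountMatrix, model, seed: int = 0) -> tuple[CountMatrix, np.ndarray]:
    """Zero each non-zero entry independently with its model-given probability.

    Returns the thinned matrix and the boolean mask of dropout events.
    """
    if isinstance(model, FixedDropout) and not 0 <= model.rate <= 1:
        raise ValueError(f"dropout rate must be in [0, 1], got {model.rate}")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(counts.counts)
    vals = counts.counts[rows, cols].astype(float)
    p = np.clip(model.probabilities(vals, rows), 0.0, 1.0)
    hit = rng.random(len(rows)) < p
    out = counts.counts.copy()
    out[rows[hit], cols[hit]] = 0
    mask = np.zeros_like(counts.counts, dtype=bool)
    mask[rows[hit], cols[hit]] = True
    return CountMatrix(out, list(counts.cell_ids), list(counts.gene_ids)), mask


def downsample_experiment(
    counts: CountMatrix,
    retain_fraction: float,
    model,
    seed: int = 0,
) -> DownsampleResult:
    """Multinomial thinning followed by extra dropout, with zero provenance."""
    rng_seed = np.random.SeedSequence([seed, 0]).generate_state(1)[0] % (2**31)
    drop_seed = np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31)
    thinned = multinomial_downsample(counts, retain_fraction, seed=int(rng_seed))
    final, dropout_mask = apply_dropout(thinned, model, seed=int(drop_seed))

    prov = np.full(counts.counts.shape, PROVENANCE_NONZERO, dtype=np.int8)
    prov[counts.counts == 0] = PROVENANCE_ORIGINAL_ZERO
    ds_zero = (counts.counts > 0) & (thinned.counts == 0)
    prov[ds_zero] = PROVENANCE_DOWNSAMPLING_ZERO
    prov[dropout_mask] = PROVENANCE_DROPOUT_ZERO
    model_name = "fixed" if isinstance(model, FixedDropout) else "logistic"
    return DownsampleResult(
        downsampled=final,
        zero_provenance=prov,
        retain_fraction=retain_fraction,
        dropout_model=model_name,
    )


# ---------------------------------------------------------------------------
# metrics

def metric_correlation_median(
    imputed: np.ndarray,
    truth: np.ndarray,
    entries: tuple[np.ndarray, np.ndarray],
    per_cell: bool = True,
    min_entries: int = 3,
) -> float:
    """Pearson correlation between imputed and true values over an entry set.

    Default: correlation within each cell (cells with fewer than
    ``min_entries`` evaluated entries, or a constant vector, are skipped),
    then the median across cells.  ``per_cell=False`` pools all entries into
    one correlation.  Returns NaN when nothing is evaluable.
    """
    rows, cols = entries
    a = np.asarray(imputed)[rows, cols].astype(float)
    b = np.asarray(truth)[rows, cols].astype(float)
    if len(a) == 0:
        return float("nan")
    if not per_cell:
        if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])
    corrs = []
    order = np.argsort(rows, kind="stable")
    rs, asrt, bsrt = rows[order], a[order], b[order]
    starts = np.flatnonzero(np.r_[True, np.diff(rs) != 0])
    bounds = np.r_[starts, len(rs)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < min_entries:
            continue
        av, bv = asrt[s:e], bsrt[s:e]
        if np.std(av) == 0 or np.std(bv) == 0:
            continue
        corrs.append(np.corrcoef(av, bv)[0, 1])
    return float(np.median(corrs)) if corrs else float("nan")


def metric_losses(
    imputed: np.ndarray,
    truth: np.ndarray,
    entries: tuple[np.ndarray, np.ndarray],
) -> tuple[float, float]:
    """(mean squared error, mean absolute deviation) over an entry set."""
    rows, cols = entries
    if len(rows) == 0:
        raise ValueError("empty entry set")
    d = np.asarray(imputed)[rows, cols].astype(float) - np.asarray(truth)[rows, cols].astype(float)
    return float(np.mean(d**2)), float(np.mean(np.abs(d)))


def metric_cv_pairs(
    before: np.ndarray,
    after: np.ndarray,
    nonzero_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene CV pairs: before over non-zero cells only, after over all cells.

    CV = sd / mean on whatever expression scale the caller supplies.  Genes
    with fewer than 2 non-zero cells before, fewer than 2 cells after, or a
    zero mean get NaN.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    n_genes = before.shape[1]
    cv_before = np.full(n_genes, np.nan)
    cv_after = np.full(n_genes, np.nan)
    for j in range(n_genes):
        nz = nonzero_mask[:, j]
        if nz.sum() >= 2:
            v = before[nz, j]
            m = v.mean()
            if m != 0:
                cv_before[j] = v.std(ddof=0) / m
        if after.shape[0] >= 2:
            v = after[:, j]
            m = v.mean()
            if m != 0:
                cv_after[j] = v.std(ddof=0) / m
    return cv_before, cv_after


def metric_jaccard_topk(list_a: Sequence, list_b: Sequence, k: int) -> float:
    """|top_k(a) & top_k(b)| / |top_k(a) | top_k(b)|."""
    if k > len(list_a) or k > len(list_b):
        raise ValueError(f"k={k} exceeds a list length ({len(list_a)}, {len(list_b)})")
    sa, sb = set(list(list_a)[:k]), set(list(list_b)[:k])
    return len(sa & sb) / len(sa | sb)


def rank_genes_wilcoxon(counts: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Built-in per-gene ranking: Wilcoxon rank-sum on log-normalized expression.

    A stand-in for external differential expression engines; returns gene
    indices ordered from most to least differential (|z| of the rank-sum
    statistic, ties broken by gene index).
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    depths = counts.sum(axis=1, keepdims=True)
    depths[depths == 0] = 1
    X = log_transform(counts / depths * 1e6)
    n1, n2 = int(groups.sum()), int((~groups).sum())
    ranks = rankdata(X, axis=0)
    r1 = ranks[groups].sum(axis=0)
    mean_r1 = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = np.abs(r1 - mean_r1) / sd
    return np.lexsort((np.arange(counts.shape[1]), -z))


def split_half_reproducibility(
    counts: CountMatrix,
    cell_labels: np.ndarray,
    pair: tuple,
    rank_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = rank_genes_wilcoxon,
    n_splits: int = 10,
    ks: Sequence[int] = JACCARD_KS,
    seed: int = 0,
    permute_labels: bool = False,
) -> dict:
    """Mean top-k Jaccard overlap of per-gene rankings across random half-splits.

    Cells of the two subpopulations in ``pair`` are halved at random within
    each type; ``rank_fn(counts_half, groups_half)`` ranks genes on each
    half and the top-k lists are compared.  ``permute_labels`` shuffles the
    type labels among the selected cells before splitting (a null control).
    """
    cell_labels = np.asarray(cell_labels)
    la, lb = pair
    idx_a = np.flatnonzero(cell_labels == la)
    idx_b = np.flatnonzero(cell_labels == lb)
    if len(idx_a) < 4 or len(idx_b) < 4:
        raise ValueError("each cell type in the pair needs at least 4 cells")
    rng = np.random.default_rng(seed)
    sums = {k: 0.0 for k in ks}
    for split in range(n_splits):
        ia = rng.permutation(idx_a)
        ib = rng.permutation(idx_b)
        if permute_labels:
            merged = rng.permutation(np.concatenate([ia, ib]))
            ia, ib = merged[: len(ia)], merged[len(ia):]
        half_a1, half_a2 = ia[: len(ia) // 2], ia[len(ia) // 2:]
        half_b1, half_b2 = ib[: len(ib) // 2], ib[len(ib) // 2:]
        lists = []
        for ha, hb in ((half_a1, half_b1), (half_a2, half_b2)):
            sel = np.concatenate([ha, hb])
            groups = np.zeros(len(sel), dtype=bool)
            groups[: len(ha)] = True
            try:
                lists.append(np.asarray(rank_fn(counts.counts[sel], groups)))
            except Exception as exc:
                raise RuntimeError(f"rank_fn failed on split {split}") from exc
        for k in ks:
            sums[k] += metric_jaccard_topk(lists[0], lists[1], k)
    return {k: sums[k] / n_splits for k in ks}


# ---------------------------------------------------------------------------
# composed experiments

def masking_experiment(
    counts: CountMatrix,
    pct: float = 0.05,
    config=None,
    seed: int = 0,
) -> dict:
    """Mask non-zero entries, impute, and score against the masked truth.

    Scores the imputed values with the per-cell-median correlation plus
    squared/L1 losses, alongside two baselines: leaving zeros in place
    (ln 0.1 on the log scale; its correlation is undefined for constant
    vectors and is reported as 0) and imputing each gene's non-zero mean.
    Imputation is restricted to the masked entries — per-entry independence
    of the imputation formula makes those values identical to a full run.
    """
    from .imputer import ImputerConfig, impute_matrix  # local import to avoid cycle
    from .preprocess import compute_rpm

    config = config or ImputerConfig()
    masked, entries = mask_nonzero(counts, pct, seed=seed)

    restrict: dict[int, list] = {}
    # map masked entries into the post-filter index space by ids
    from .preprocess import filter_cells_by_library, filter_genes_by_expression

    filt = filter_genes_by_expression(masked, config.min_expressed_fraction)
    filt = filter_cells_by_library(filt, config.min_library_size)
    cell_pos = {c: i for i, c in enumerate(filt.cell_ids)}
    gene_pos = {g: j for j, g in enumerate(filt.gene_ids)}
    kept_rows, kept_cols, kept_vals = [], [], []
    for r, c, v in zip(entries.rows, entries.cols, entries.true_counts):
        ci = cell_pos.get(counts.cell_ids[r])
        gj = gene_pos.get(counts.gene_ids[c])
        if ci is None or gj is None:
            continue
        kept_rows.append(ci)
        kept_cols.append(gj)
        kept_vals.append(v)
        restrict.setdefault(ci, []).append(gj)
    rows = np.asarray(kept_rows, dtype=int)
    cols = np.asarray(kept_cols, dtype=int)
    restrict_arr = {i: np.unique(np.asarray(g)) for i, g in restrict.items()}

    result = impute_matrix(masked, config, genes_restrict_per_cell=restrict_arr)

    # truth on the log scale, from the original (unmasked) counts aligned to the output
    orig_align = counts.subset_cells(
        np.array([counts.cell_ids.index(c) for c in result.cell_ids])
    ).subset_genes(np.array([counts.gene_ids.index(g) for g in result.gene_ids]))
    rpm, _ = compute_rpm(orig_align)
    truth_X = log_transform(rpm)

    ent = (rows, cols)
    zero_baseline = np.full(result.imputed.shape, LOG_ZERO)
    nz = filt.counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rpm_m, _ = compute_rpm(filt)
        Xm = log_transform(rpm_m)
        gene_mean = np.where(
            nz.sum(axis=0) > 0,
            np.where(nz, Xm, 0).sum(axis=0) / np.maximum(nz.sum(axis=0), 1),
            LOG_ZERO,
        )
    mean_baseline = np.broadcast_to(gene_mean, result.imputed.shape)

    corr = metric_correlation_median(result.imputed, truth_X, ent)
    corr_zero = metric_correlation_median(zero_baseline, truth_X, ent)
    corr_mean = metric_correlation_median(mean_baseline, truth_X, ent)
    mse, l1 = metric_losses(result.imputed, truth_X, ent)
    return {
        "correlation_median": corr,
        "correlation_zero_baseline": 0.0 if np.isnan(corr_zero) else corr_zero,
        "correlation_gene_mean_baseline": corr_mean,
        "squared_loss": mse,
        "l1_loss": l1,
        "n_masked_evaluated": int(len(rows)),
        "result": result,
        "entries": ent,
        "truth_X": truth_X,
    }


def cv_preservation_experiment(dataset: SyntheticDataset, config=None) -> dict:
    """Impute a synthetic dataset fully and compare per-gene CV before/after.

    CV is computed on the back-transformed expression scale exp(X) - 0.1
    (RPM); before-CV uses non-zero cells of the observed data, after-CV all
    cells of the imputed matrix.  Reports the fraction of genes whose CV
    stays within +-25% and the fraction whose CV does not decrease.
    """
    from .imputer import ImputerConfig, impute_matrix
    from .preprocess import compute_rpm, filter_cells_by_library, filter_genes_by_expression

    config = config or ImputerConfig()
    result = impute_matrix(dataset.counts, config)

    filt = filter_genes_by_expression(dataset.counts, config.min_expressed_fraction)
    filt = filter_cells_by_library(filt, config.min_library_size)
    rpm, _ = compute_rpm(filt)
    after = np.exp(result.imputed) - 0.1
    cv_before, cv_after = metric_cv_pairs(rpm, after, filt.counts > 0)
    ok = np.isfinite(cv_before) & np.isfinite(cv_after) & (cv_before > 0)
    rel = np.abs(cv_after[ok] - cv_before[ok]) / cv_before[ok]
    return {
        "cv_before": cv_before,
        "cv_after": cv_after,
        "frac_within_25pct": float(np.mean(rel <= 0.25)) if ok.any() else float("nan"),
        "frac_not_decreased": float(np.mean(cv_after[ok] >= cv_before[ok] * (1 - 1e-12)))
        if ok.any() else float("nan"),
        "n_genes_evaluated": int(ok.sum()),
        "result": result,
    }
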