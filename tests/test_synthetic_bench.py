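import numpy as np
import pytest

from cellimp.matrix_io import CountMatrix
from cellimp.synthetic_bench import (
    FixedDropout,
    LogisticDropout,
    PROVENANCE_DOWNSAMPLING_ZERO,
    PROVENANCE_DROPOUT_ZERO,
    PROVENANCE_NONZERO,
    PROVENANCE_ORIGINAL_ZERO,
    apply_dropout,
    downsample_experiment,
    fit_logistic_dropout,
    mask_nonzero,
    metric_correlation_median,
    metric_cv_pairs,
    metric_jaccard_topk,
    metric_losses,
    multinomial_downsample,
    rank_genes_wilcoxon,
    simulate_counts,
    split_half_reproducibility,
)


def _cm(arr):
    arr = np.asarray(arr)
    return CountMatrix(arr, [f"c{i}" for i in range(arr.shape[0])],
                       [f"g{j}" for j in range(arr.shape[1])])


# ----------------------------------------------------------------- generator

def test_simulate_deterministic():
    a = simulate_counts(n_cells=50, n_genes=80, seed=4)
    b = simulate_counts(n_cells=50, n_genes=80, seed=4)
    np.testing.assert_array_equal(a.counts.counts, b.counts.counts)
    np.testing.assert_array_equal(a.dropout_mask, b.dropout_mask)
    c = simulate_counts(n_cells=50, n_genes=80, seed=5)
    assert not np.array_equal(a.counts.counts, c.counts.counts)


def test_simulate_no_dropout_means_counts_equal_truth():
    ds = simulate_counts(n_cells=30, n_genes=60, dropout_logistic_params=None, seed=1)
    assert not ds.dropout_mask.any()
    np.testing.assert_array_equal(ds.counts.counts, ds.truth_counts.counts)


def test_simulate_mask_consistency():
    ds = simulate_counts(n_cells=40, n_genes=70, seed=2)
    same = ~ds.dropout_mask
    np.testing.assert_array_equal(ds.counts.counts[same], ds.truth_counts.counts[same])
    assert np.all(ds.counts.counts[ds.dropout_mask] == 0)
    assert np.all(ds.truth_counts.counts[ds.dropout_mask] > 0)
    assert set(ds.cell_labels) == set(range(3))


def test_simulate_per_gene_means_match_specification():
    ds = simulate_counts(n_cells=2000, n_genes=150, n_subpops=1, seed=8,
                         dropout_logistic_params=None, dispersion=0.3,
                         depth_range=(1e4, 1e4))
    props = ds.params["subpop_proportions"][0]
    emp = (ds.truth_counts.counts / 1e4).mean(axis=0)
    # MC standard error of the mean of an over-dispersed count / depth
    var = props / 1e4 + 0.3 * props**2
    se = np.sqrt(var / 2000)
    assert np.all(np.abs(emp - props) < 4 * se + 1e-12)


def test_simulate_validates_parameters():
    with pytest.raises(ValueError):
        simulate_counts(n_cells=0)
    with pytest.raises(ValueError):
        simulate_counts(dispersion=-0.1)


# ------------------------------------------------------------------ masking

def test_mask_bookkeeping_reconstructs_input():
    rng = np.random.default_rng(0)
    cm = _cm(rng.poisson(2, size=(20, 30)))
    masked, ent = mask_nonzero(cm, 0.10, seed=1)
    assert len(ent.rows) == int(round(0.10 * np.count_nonzero(cm.counts)))
    assert np.all(masked.counts[ent.rows, ent.cols] == 0)
    assert np.all(ent.true_counts > 0)
    rebuilt = masked.counts.copy()
    rebuilt[ent.rows, ent.cols] = ent.true_counts
    np.testing.assert_array_equal(rebuilt, cm.counts)


def test_mask_rejects_empty_selection():
    cm = _cm(np.array([[1, 0], [0, 0]]))
    with pytest.raises(ValueError, match="at least one"):
        mask_nonzero(cm, 0.05, seed=0)


def test_mask_uniform_inclusion_frequency():
    cm = _cm(np.arange(1, 26).reshape(5, 5))  # 25 non-zeros
    pct, n_seeds = 0.2, 600
    hits = np.zeros((5, 5))
    for s in range(n_seeds):
        _, ent = mask_nonzero(cm, pct, seed=s)
        hits[ent.rows, ent.cols] += 1
    p = 5 / 25
    sd = np.sqrt(p * (1 - p) / n_seeds)
    assert np.all(np.abs(hits / n_seeds - p) < 3.5 * sd)


# ------------------------------------------------------------- downsampling

def test_downsample_retain_one_preserves_totals():
    rng = np.random.default_rng(1)
    cm = _cm(rng.poisson(3, size=(15, 25)))
    out = multinomial_downsample(cm, 1.0, seed=0)
    np.testing.assert_array_equal(out.counts.sum(axis=0), cm.counts.sum(axis=0))


def test_downsample_entry_expectations():
    cm = _cm(np.array([[40, 0, 10], [10, 0, 10], [50, 0, 0]]))
    reps = 600
    acc = np.zeros((3, 3))
    for s in range(reps):
        acc += multinomial_downsample(cm, 0.6, seed=s).counts
    mean = acc / reps
    expect = 0.6 * cm.counts
    # binomial-ish MC standard error per entry
    se = np.sqrt(np.maximum(expect * 0.4, 1e-9) / reps)
    assert np.all(np.abs(mean - expect) < 4 * se + 0.5)


def test_downsample_zero_total_gene_stays_zero():
    out = multinomial_downsample(_cm(np.array([[0, 3], [0, 5]])), 0.5, seed=2)
    assert np.all(out.counts[:, 0] == 0)


def test_downsample_validates_fraction():
    with pytest.raises(ValueError):
        multinomial_downsample(_cm(np.ones((2, 2), dtype=int)), 0.0, seed=0)


# ------------------------------------------------------------ dropout model

def test_apply_dropout_rate_zero_is_identity():
    rng = np.random.default_rng(2)
    cm = _cm(rng.poisson(2, size=(10, 10)))
    out, mask = apply_dropout(cm, FixedDropout(0.0), seed=0)
    np.testing.assert_array_equal(out.counts, cm.counts)
    assert not mask.any()


def test_apply_dropout_fixed_rate_within_3sd():
    arr = np.ones((400, 250), dtype=int)  # 1e5 non-zero entries
    out, mask = apply_dropout(_cm(arr), FixedDropout(0.8), seed=3)
    n = arr.size
    frac = mask.sum() / n
    sd = np.sqrt(0.8 * 0.2 / n)
    assert abs(frac - 0.8) < 3 * sd


def test_logistic_fit_recovers_planted_coefficients():
    rng = np.random.default_rng(4)
    n_cells, n_genes = 200, 4000
    a, b = 1.0, -0.08
    nz_vals = rng.uniform(1, 60, n_genes)
    pz = 1 / (1 + np.exp(-(a + b * nz_vals)))
    counts = np.zeros((n_cells, n_genes), dtype=int)
    for j in range(n_genes):
        zeros = rng.random(n_cells) < pz[j]
        counts[~zeros, j] = int(round(nz_vals[j]))
    cm = _cm(counts)
    coeffs = fit_logistic_dropout(cm, np.zeros(n_cells, dtype=int))
    a_hat, b_hat = coeffs[0]
    assert a_hat == pytest.approx(a, rel=0.10)
    assert b_hat == pytest.approx(b, rel=0.10)


def test_logistic_fit_constant_fraction_flat_slope():
    rng = np.random.default_rng(5)
    n_cells, n_genes = 400, 800
    counts = np.zeros((n_cells, n_genes), dtype=int)
    vals = rng.integers(1, 50, n_genes)
    for j in range(n_genes):
        zeros = rng.random(n_cells) < 0.5
        counts[~zeros, j] = vals[j]
    coeffs = fit_logistic_dropout(_cm(counts), np.zeros(n_cells, dtype=int))
    a_hat, b_hat = coeffs[0]
    prob_mid = 1 / (1 + np.exp(-(a_hat + b_hat * 25)))
    assert prob_mid == pytest.approx(0.5, abs=0.05)
    assert abs(b_hat) < 0.01


def test_logistic_fit_monotone_decreasing_gives_negative_slope():
    rng = np.random.default_rng(6)
    n_cells, n_genes = 150, 1500
    vals = rng.uniform(1, 80, n_genes)
    pz = 1 / (1 + np.exp(-(2.0 - 0.1 * vals)))
    counts = np.zeros((n_cells, n_genes), dtype=int)
    for j in range(n_genes):
        zeros = rng.random(n_cells) < pz[j]
        counts[~zeros, j] = int(round(vals[j]))
    coeffs = fit_logistic_dropout(_cm(counts), np.zeros(n_cells, dtype=int))
    assert coeffs[0][1] < 0


def test_logistic_fit_rejects_degenerate_subpop():
    counts = np.ones((10, 20), dtype=int)  # no zeros at all
    with pytest.raises(ValueError, match="degenerate"):
        fit_logistic_dropout(_cm(counts), np.zeros(10, dtype=int))


def test_provenance_partition():
    ds = simulate_counts(n_cells=60, n_genes=100, seed=7)
    res = downsample_experiment(ds.counts, 0.7, FixedDropout(0.5), seed=8)
    prov = res.zero_provenance
    # labels partition the matrix
    assert np.isin(prov, [PROVENANCE_NONZERO, PROVENANCE_ORIGINAL_ZERO,
                          PROVENANCE_DOWNSAMPLING_ZERO, PROVENANCE_DROPOUT_ZERO]).all()
    assert np.array_equal(prov == PROVENANCE_ORIGINAL_ZERO, ds.counts.counts == 0)
    # dropout zeros were non-zero after the multinomial step and are zero now
    assert np.all(res.downsampled.counts[prov == PROVENANCE_DROPOUT_ZERO] == 0)
    assert np.all(res.downsampled.counts[prov == PROVENANCE_NONZERO] > 0)
    assert np.all(ds.counts.counts[prov == PROVENANCE_DOWNSAMPLING_ZERO] > 0)


def test_logistic_dropout_model_uses_per_subpop_coefficients():
    labels = np.array([0, 0, 1, 1])
    model = LogisticDropout({0: (10.0, 0.0), 1: (-10.0, 0.0)}, labels)
    cm = _cm(np.full((4, 50), 5))
    out, mask = apply_dropout(cm, model, seed=0)
    assert mask[:2].mean() > 0.95   # subpop 0: certain dropout
    assert mask[2:].mean() < 0.05   # subpop 1: none


# ------------------------------------------------------------------- metrics

def test_correlation_median_exact_cases():
    rng = np.random.default_rng(8)
    truth = rng.normal(size=(6, 40))
    entries = np.nonzero(np.ones_like(truth, dtype=bool))
    assert metric_correlation_median(truth, truth, entries) == pytest.approx(1.0)
    assert metric_correlation_median(-truth + 2.0, truth, entries) == pytest.approx(-1.0)


def test_correlation_median_matches_direct_formula():
    rng = np.random.default_rng(9)
    imp = rng.normal(size=(5, 30))
    truth = rng.normal(size=(5, 30))
    sel = rng.random((5, 30)) < 0.6
    entries = np.nonzero(sel)
    got = metric_correlation_median(imp, truth, entries)
    per_cell = []
    for i in range(5):
        cols = np.flatnonzero(sel[i])
        if len(cols) < 3:
            continue
        a, b = imp[i, cols], truth[i, cols]
        per_cell.append(
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
    assert got == pytest.approx(np.median(per_cell), abs=1e-12)
    pooled = metric_correlation_median(imp, truth, entries, per_cell=False)
    a, b = imp[entries], truth[entries]
    direct = np.corrcoef(a, b)[0, 1]
    assert pooled == pytest.approx(direct, abs=1e-12)


def test_losses_match_direct_formula():
    rng = np.random.default_rng(10)
    imp = rng.normal(size=(4, 20))
    truth = rng.normal(size=(4, 20))
    entries = np.nonzero(np.ones_like(imp, dtype=bool))
    mse, l1 = metric_losses(imp, truth, entries)
    assert mse == pytest.approx(np.mean((imp - truth) ** 2), abs=1e-12)
    assert l1 == pytest.approx(np.mean(np.abs(imp - truth)), abs=1e-12)
    mse0, l10 = metric_losses(truth, truth, entries)
    assert mse0 == 0 and l10 == 0
    mse_d, l1_d = metric_losses(truth + 2.5, truth, entries)
    assert mse_d == pytest.approx(6.25) and l1_d == pytest.approx(2.5)


def test_cv_pairs_direct_and_scale_invariance():
    before = np.array([[1.0, 5.0], [2.0, 0.0], [3.0, 7.0]])
    after = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]])
    nz = before > 0
    cv_b, cv_a = metric_cv_pairs(before, after, nz)
    vals = np.array([1.0, 2.0, 3.0])
    assert cv_b[0] == pytest.approx(vals.std() / vals.mean(), abs=1e-12)
    cv_b2, cv_a2 = metric_cv_pairs(before * 3.0, after * 3.0, nz)
    np.testing.assert_allclose(cv_b2, cv_b, atol=1e-12)
    np.testing.assert_allclose(cv_a2, cv_a, atol=1e-12)
    const = np.ones((3, 1))
    cv_b3, cv_a3 = metric_cv_pairs(const, const, const > 0)
    assert cv_b3[0] == 0 and cv_a3[0] == 0


def test_jaccard_worked_cases():
    assert metric_jaccard_topk(["a", "b", "c"], ["b", "c", "d"], 3) == pytest.approx(0.5)
    assert metric_jaccard_topk(list("abcde"), list("abcde"), 5) == 1.0
    assert metric_jaccard_topk(list("abc"), list("xyz"), 3) == 0.0
    with pytest.raises(ValueError):
        metric_jaccard_topk(list("ab"), list("abc"), 3)


# ---------------------------------------------------- split-half experiment

def test_split_half_fixed_ranking_gives_one():
    ds = simulate_counts(n_cells=40, n_genes=300, n_subpops=2, seed=11)
    fixed = lambda counts, groups: np.arange(300)
    out = split_half_reproducibility(ds.counts, ds.cell_labels, (0, 1),
                                     rank_fn=fixed, n_splits=3, ks=(100,), seed=0)
    assert out[100] == pytest.approx(1.0)


def test_split_half_random_ranking_near_null_overlap():
    ds = simulate_counts(n_cells=24, n_genes=10000, n_subpops=2, seed=12,
                         dropout_logistic_params=None, depth_range=(1e3, 1e3))
    rng = np.random.default_rng(13)
    rand_fn = lambda counts, groups: rng.permutation(10000)
    k, G = 100, 10000
    out = split_half_reproducibility(ds.counts, ds.cell_labels, (0, 1),
                                     rank_fn=rand_fn, n_splits=10, ks=(k,), seed=1)
    e_int = k * k / G  # hypergeometric expectation of |top_a & top_b|
    expect = e_int / (2 * k - e_int)
    assert abs(out[k] - expect) < 0.01


def test_split_half_permutation_control_runs():
    ds = simulate_counts(n_cells=40, n_genes=500, n_subpops=2, seed=14)
    out = split_half_reproducibility(ds.counts, ds.cell_labels, (0, 1),
                                     n_splits=2, ks=(50,), seed=2, permute_labels=True)
    assert 0.0 <= out[50] <= 1.0


def test_wilcoxon_ranking_puts_separated_gene_first():
    rng = np.random.default_rng(15)
    counts = rng.poisson(5, size=(30, 50))
    groups = np.zeros(30, dtype=bool)
    groups[:15] = True
    counts[groups, 7] += 200  # strongly differential gene
    order = rank_genes_wilcoxon(counts, groups)
    assert order[0] == 7
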