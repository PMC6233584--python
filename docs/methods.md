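# Methods

## The imputation model

`cellimp` imputes the zero entries of a single-cell RNA-seq count matrix
C (cells × genes) by borrowing information across cells.  Counts are
normalized to reads-per-million, R_ij = C_ij / N_i × 10⁶ with
N_i = Σ_j C_ij, and log-transformed, X_ij = ln(R_ij + 0.1).  Natural log
is used throughout; the pseudo-value 0.1 sends zero counts to
ln 0.1 ≈ −2.3026.

For each target cell i, its expression over genes is modeled in
expectation as a weighted sum of all other cells,

    E[X_ij] = Σ_{l≠i} X_lj · b_il ,     b_il ≥ 0,  Σ_l b_il = 1,

a sparse nonnegative regression on the probability simplex.  Weights below
the hard threshold t = 0.001 are set exactly to zero and the survivors
renormalized, giving a small neighborhood per cell.  Because each cell is
fit separately the neighborhoods are deliberately asymmetric.  Each zero
entry of cell i is then imputed as X̂_ij = Σ_l x*_lj b̂_il, where x*_lj is
the neighbor's predictor value (see "Dropout adjustment"); observed
non-zero entries are never altered, and no smoothing is applied to them.

The mean model is fit only over "fitting genes" — genes whose zero-count
fraction is strictly below 10% — so that missing values do not distort the
weights.  If fewer than 500 genes qualify the threshold is relaxed in
steps of 0.05 with a logged warning; this floor keeps the regression
sensible on very sparse matrices and is a package choice.

## Two-stage neighbor selection

Fitting the simplex regression against all n−1 cells at once is both slow
and prone to overfitting, so selection happens in two stages.

**Pre-selection.**  The target cell's log expression over a random sample
of up to 5,000 fitting genes (one sample per run, drawn from the run
seed; `--resample-per-cell` redraws per cell) is regressed on all other
cells with an L1 (lasso) or L1+L2 (elastic net, mixing 0.5) penalty.
Genes act as observations and cells as predictors; the penalty strength is
chosen by 10-fold cross-validation over genes, and the cells with non-zero
coefficients of either sign at the selected penalty form the candidate
pool.  Nonnegativity is deliberately *not* imposed here — this stage only
ranks cells; the sign constraint belongs to the estimation stage.  An
intercept is included (as the standard default for a ranking regression);
the estimation stage has none because the simplex constraint plays that
role.  If the selection comes back empty (e.g. a near-constant cell), the
fallback is the 50 cells with highest Pearson correlation to the target
over the fitting genes.

Implementation: every target shares the same design matrix (columns =
cells), so per-fold column means and Gram matrices are computed once per
run and reused for all targets, with the target's row/column deleted per
query.  The fold assignment over genes is drawn once per run from the run
seed and shared across cells; this makes penalty selection comparable
between cells and is what makes the precomputation valid.  The lasso path
itself is an exact LARS homotopy on the precomputed Gram
(`_lars_kernel.lars_lasso_gram`, validated against
`sklearn.linear_model.lars_path_gram` in the test suite); the coefficient
path is piecewise linear in the penalty, so interpolating it onto the CV
grid is exact.  The CV grid spans three decades below the null penalty
(30 log-spaced points); it is searched in stages from the top and extended
deeper only while the CV minimum sits at the boundary of what has been
computed, because deep path segments among collinear cells are expensive
and essentially never selected.  The elastic-net variant uses sklearn's
coordinate-descent `enet_path` with the same staged early stopping.

**Estimation.**  Over the candidate pool the constrained least squares

    min_b Σ_{j ∈ fitting} (X_ij − Σ_l X_lj b_il)²,   b ≥ 0, Σ b = 1

is solved as a quadratic program.  The equality constraint is eliminated
against a reference candidate r — the pool cell most correlated with the
target, ties broken toward the lowest cell index: with
W_j = X_ij − X_rj and Y_lj = X_lj − X_rj (l ≠ r),

    min_β  ½ βᵀ(Σ_j Y_.j Y_.jᵀ)β − (Σ_j W_j Y_.jᵀ)β ,
    s.t.   β ≥ 0,  Σβ ≤ 1,

and b_r = 1 − Σβ ≥ 0 is recovered afterwards (β ≤ 1 is implied).  A pool
of exactly one candidate has no reference to difference against and is
posed directly as the scalar box-constrained QP in that candidate's
weight, whose analytic minimizer is clipped to [0, 1]; the threshold step
restores Σb = 1.

The solver is accelerated projected gradient (FISTA with adaptive
restart) over {β ≥ 0, Σβ ≤ 1}, with an active-set polish that solves the
equality-constrained least squares on the guessed support.  Convergence
is declared when the natural-map residual ‖β − P(β − ∇f)‖∞ falls below
`qp_tol` (default 1e-8, scaled by the linear-term magnitude); this
residual is zero exactly at KKT points, so any convex-QP method passing
the same check would be interchangeable.  Non-convergence raises an error
carrying the iteration count and residual; in the full pipeline such
cells are collected and reported rather than silently zero-filled, and a
run aborts only if more than half of all cells fail.

Weight estimation always uses the raw X over fitting genes — dropout
adjustment applies only at imputation time, so that the weights are
driven by well-measured genes.

## Dropout adjustment

A neighbor's zero count is ambiguous: dropout (transcript present but not
captured) or genuine low expression.  Before being used as a predictor,
zero counts are replaced by a model-based estimate of the underlying
rate.  For one gene j within the neighborhood of target cell i, neighbor
counts are modeled as a zero-inflated Poisson mixed model

    C_lj ~ p_ij δ₀ + (1 − p_ij) · PoisLN(N_l λ_lj, ψ_ij),

with a shared dropout probability p_ij and gene-level over-dispersion
ψ_ij specific to that neighborhood.  The Poisson mixed-effects component
is realized as a log-normal rate mixture, λ_lj = exp(μ_ij + ε_lj),
ε_lj ~ N(0, ψ_ij) — one standard reading of a Poisson mixed model; the
module isolates this choice so a gamma (negative-binomial) realization
could be swapped in without touching callers, and the realization is a
package decision, not a claim about any external specification.

The integral over ε is evaluated with fixed 31-point Gauss–Hermite
quadrature.  Since the quadrature weights sum to one, the working
likelihood is itself a proper finite Poisson mixture, so the EM ascent
property holds exactly for it — the monotonicity the tests assert is not
merely approximate.

**EM details.**  The E-step computes posterior dropout responsibilities
for zero counts; the M-step updates p in closed form (capped at 0.99 to
rule out the degenerate all-dropout solution) and (μ, ψ) by damped 2-D
Newton ascent on (μ, ln ψ) with analytic gradient/Hessian and
backtracking that never accepts a decrease of the expected complete-data
log-likelihood.  Initialization is deterministic: p₀ = half the observed
zero fraction, μ₀ = log mean of non-zero count/depth, ψ₀ = 0.5.  Plain EM
can crawl on flat likelihood ridges, so iterations are taken in blocks of
two EM steps followed by a SQUAREM-style extrapolation in (p, μ, ln ψ)
that is accepted only when the observed log-likelihood does not decrease.
Convergence: log-likelihood improvement < `em_tol` (default 1e-6) or
`em_max_iter` (default 500) EM steps, after which the last iterate is
returned flagged as non-converged.  μ is bounded in [−30, 10], ψ in
[1e-6, 50].  An all-zero gene returns p = 0.99 with μ at the floor and a
warning.  All genes of one neighborhood are fitted in a single compiled
pass (`_zippmm_kernel`), and fits are memoized per (neighbor set, gene).

**Posterior rate.**  For a zero count the predictor becomes the posterior
mean of λ marginalized over the dropout indicator,

    E[λ | c=0] = r · E[λ] + (1 − r) · E[λ | c=0, no dropout],

with r the posterior dropout responsibility; the replacement is applied
unconditionally (the marginalization already weights the two branches).
Mapped back to the predictor scale as ln(10⁶ λ̂ + 0.1), since λ is a
per-read rate and 10⁶λ its RPM.  Non-zero counts keep their raw X value.
The target cell's own dropout state is not modeled: the imputed value is
the weighted-mean prediction.

## Synthetic data generator

`simulate_counts` emulates the structure the method assumes: a small
number of cell subpopulations with shared expression profiles,
library-size variation, over-dispersion, and expression-dependent
dropout.  Gene relative abundances are log-normal (sd `base_log_sd`,
default 1.5); each subpopulation shifts a `de_fraction` (default 0.3) of
genes by N(0, `logmean_spread`).  Per-cell depths are log-uniform on
`depth_range` (default 5×10⁴–2×10⁵ reads).  Counts are gamma-Poisson with
dispersion 0.3 by default (variance = m + 0.3 m²).  Dropout is injected
per entry with probability sigmoid(a + b ln(m + 0.1)) with default
(a, b) = (1.0, −1.5) — decreasing in the underlying mean m, so
high-expression genes are nearly dropout-free, as in real data.  Truth
matrix and dropout mask are recorded; everything is deterministic given
the seed.

What the generator does **not** emulate: batch effects, cell-cycle or
continuous-trajectory structure, gene–gene correlation beyond
subpopulation profiles, UMI deduplication, ambient RNA, or doublets.
Passing tests therefore demonstrates correctness of the machinery and
recovery under the stated generative assumptions, not performance on any
particular real dataset.

## Evaluation experiments

**Masking.**  A fixed percentage (2/5/10%) of non-zero entries is set to
zero; the imputed values at those entries are compared with the truth by
Pearson correlation computed per cell and then medianed across cells
(cells with fewer than 3 evaluated entries, or a constant vector, are
skipped; a pooled-over-entries variant is also provided), plus squared
and L1 losses.  Two baselines are reported: leaving the zeros (constant
ln 0.1, whose per-cell correlation is undefined and reported as 0) and
imputing each gene's non-zero mean.  The harness imputes only the masked
entries: the imputation formula is per-entry, so these values are
identical to a full run at a fraction of the cost.

**Two-step down-sampling.**  Per gene, reads are re-drawn from a
multinomial with trials = round(retain × gene total) and probabilities
equal to each cell's share — the expected per-cell proportion is
unchanged.  The `retain` parameter is the *retained* fraction of reads
(0.5 means the library shrinks to 50%); supported settings include 0.5,
0.6, 0.7, 0.8, 0.9, 0.95.  Extra dropout is then applied to surviving
non-zeros, either at a fixed rate of 0.8 or with per-subpopulation
logistic rates: within each subpopulation, per gene, the zero fraction is
regressed on the mean of non-zero values by fractional-response binomial
GLM (zero fractions are proportions, not 0/1 outcomes — hence the
quasi-likelihood fit), and the fitted curve converts each non-zero value
into a dropout probability.  Every zero in the result carries a
provenance label (original / down-sampling / dropout).

**CV preservation.**  Per gene, the coefficient of variation (sd/mean)
across all cells after imputation is compared with the CV of the non-zero
cells before imputation.  CV is computed on the back-transformed
expression scale exp(X) − 0.1 (RPM) by default, since CV is not
meaningful on a log scale that takes negative values.  The sanity
property: when zeros are dropouts the two CVs should roughly agree (the
imputed values follow the non-zero distribution); when zeros are true low
expression the post-imputation CV should be at least as large.

**Split-half reproducibility.**  For a pair of subpopulations, cells are
halved at random within each type; any per-gene ranking function is run
on each half and the top-k lists compared by Jaccard index
(|∩|/|∪|, k ∈ {100, 200, 500, 1000}), averaged over 10 splits.  A
label-permutation control is available.  The built-in ranking is a
Wilcoxon rank-sum statistic on log-normalized expression — a stand-in so
the harness is self-contained; dedicated differential-expression engines
can be plugged in as `rank_fn`.

## Problem sizes

The test suite exercises the heavy experiments at 500 cells × 1,500 genes
(CV preservation, two zero regimes) and 1,000 cells × 2,000 genes with 5%
masking (masking experiment), the parameter-recovery study at 500
neighbors × 20 replicates for p ∈ {0.1, 0.3, 0.5}, and the QP oracle on
200 random instances against a 0.005-step simplex grid.
`scripts/acceptance.py` recomputes the same quantities at 400 × 1,500
(masking) and 300 × 1,000 (CV preservation) — sizes chosen so a complete
from-scratch rerun stays comfortable on a single core while leaving the
conclusions unchanged.

For the "all zeros are dropouts" CV regime the generator uses high depths
(1–3×10⁵), a narrow abundance spread (`base_log_sd` 0.6) and logistic
dropout (2.0, −1.2), which makes natural sampling zeros negligible
(~10⁻⁴) so that observed zeros are injected dropouts.  The "true low
expression" regime plants biological zeros — true absence of expression —
as genes silenced within a subpopulation (`silent_fraction` 0.25, rate
scaled by 10⁻³) with no injected dropout; a zero cell's neighbors are then
themselves unexpressed, imputation correctly returns ~0, and the per-gene
CV can only grow.  Marginal sampling zeros (a low-mean gene that happens
to draw zero reads in a cell whose underlying rate matches its neighbors)
deliberately belong to neither regime: for such zeros the correct imputed
value is mid-range and CV comparisons are uninformative.

## Known limitations

* Single imputation only: no uncertainty propagation over imputed values.
* Cell-based only; a gene-neighbor variant would need its own
  pre-selection geometry.
* The dropout model is fit per neighborhood and can be weakly identified
  for genes with very few zeros or very few neighbors; such fits are
  returned flagged rather than hidden, and their posterior means remain
  bounded and well-behaved.
* The EM tolerance is an absolute log-likelihood increment, so extremely
  deep neighborhoods (thousands of cells) would effectively tighten it.
* `--threads` is accepted for interface stability but execution is serial
  over cells; results are thread-count-invariant by construction because
  per-cell seeds derive from (run seed, cell index).
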