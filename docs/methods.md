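# Methods

This document states the statistical model implemented by `screenmle`, derives
the estimation algorithm, and records every default, numerical choice, and
known limitation.

## 1. Data model and notation

A pooled CRISPR screen consists of

- a guide library: sgRNAs `i = 1..n`, each targeting one gene, with a unique
  id and a unique spacer sequence (uniform length, alphabet ACGT), optionally
  annotated with a predicted-efficiency score;
- a count matrix `x_ij` of reads per sgRNA `i` and sample `j = 1..J`
  (non-negative integers);
- a binary design matrix `d_jr` over conditions `r = 1..R`: `d_jr = 1` when
  condition `r` acts on sample `j`. Baseline samples (plasmid or day-0) have
  all-zero rows. Replicates are samples sharing a design row.

For one gene with guides `i = 1..N`, counts are modelled as independent
negative binomials `x_ij ~ NB(mu_ij, alpha_i)` with variance
`mu + alpha * mu^2`, and

```
log mu_ij = log s_j + beta_i0 + z_i * sum_r d_jr * beta_r
```

where `s_j` is a size factor, `beta_i0` a per-guide baseline abundance,
`beta_r` the gene's selection coefficient in condition `r`, and
`z_i ∈ {0, 1}` a latent indicator that guide `i` actually disrupts its target
("efficient"). An inefficient guide keeps its baseline abundance in every
sample. `z_i ~ Bernoulli(p_i)` with prior `p_i` taken from the library's
efficiency scores when present (a score `v ∈ (−2, 2)` maps to
`p = (v + 2) / 4`; probability-scale scores pass through) and `p_i = 1`
otherwise, i.e. by default every guide is assumed to cut.

### Extended design matrix

Stacking the gene's observations guide-fastest
(`x_11, x_21, …, x_N1, x_12, …, x_NJ`) and its coefficients as
`beta = (beta_10, …, beta_N0, beta_1, …, beta_R)`, the efficient-component
linear predictor is `h = D' beta` where `D'` is the `(N·J) × (N + R)`
extended design: `N` baseline indicator columns (an identity block repeated
per sample) followed by the condition columns `d_jr` repeated per guide. The
inefficient component uses `D'` with the condition columns zeroed.

## 2. Size factors (median-ratio)

The pseudo-reference for guide `i` is its geometric mean across samples,
computed only over guides with strictly positive counts in **every** sample.
Then `s_j = median_i ( x_ij / xhat_i )`. With `mode="control"` the median is
restricted to a user-supplied control-guide set (useful when most of the
library responds to selection). Failure modes are explicit errors: no
all-positive guide, or a sample whose median ratio is 0. Normalized counts are
`x_ij / s_j`.

## 3. Dispersion: mean–variance trend

Per-guide dispersions are estimated once, before the final fit, from the
empirical mean–variance relationship:

1. **Prefit.** Fit every gene with all guides assumed efficient and a small
   fixed dispersion (`dispersion_prefit_alpha = 0.01`), giving fitted means
   `muhat_ij = s_j * exp(beta_i0 + d_j · beta)`.
2. **Residual variances.** For each observation,
   `sigma2_ij = (x_ij − muhat_ij)^2`, scaled by `n_obs / (n_obs − p)` for the
   gene (with `p = N + R` parameters consumed by the prefit) so that the
   squared residuals are approximately unbiased for the variance.
3. **Trend.** Model `sigma2 = mu + k * mu^b`. The exponent `b` comes from an
   ordinary least-squares fit of `log(sigma2 − mu)` on `log mu` over the
   observations with positive excess variance. The intercept `k` is then
   re-estimated on the raw scale as `k = mean( (sigma2 − mu) / mu^b )` over
   all positive-mean observations: the log-scale estimate of `k` is biased
   low both by Jensen's inequality and by the truncation to positive excess,
   and the raw-scale moment step removes that bias (without it, recovered
   dispersions ran 2–3× low at true alpha 0.1–0.2).
4. **Per-guide alpha.** `alpha_i = mean_j ( k * muhat_ij^(b−2) )`, floored at
   `alpha_floor = 1e−6`. If fewer than two observations show excess variance
   the trend is unidentifiable and all guides fall back to the prefit
   constant.

On simulated screens (500 guides, 4 samples) the median fitted alpha is
0.011 / 0.10 / 0.19 / 0.49 at true 0.01 / 0.1 / 0.2 / 0.5. At true alpha = 0
the estimate cannot reach the floor — sampling noise in the squared residuals
keeps the median near 3e−4 — but it stays an order of magnitude below the
smallest NB level and the monotone ordering in the true alpha is preserved.

## 4. Maximum-likelihood fit (EM over efficiency, IRLS over beta)

For one gene, with component log-likelihoods per guide
`l1_i(beta) = sum_j log NB(x_ij; mu1_ij, alpha_i)` (efficient) and
`l0_i(beta)` (inefficient), the penalized observed-data objective is

```
L(beta) = sum_i log( p_i * exp(l1_i) + (1 − p_i) * exp(l0_i) ) − (lambda/2) * |beta|^2
```

with ridge penalty `lambda = 0.1` on all coefficients (the penalty keeps
degenerate genes — e.g. all-zero counts in one arm — finite and identifiable).

**E-step.** `e_i = p_i exp(l1_i) / (p_i exp(l1_i) + (1 − p_i) exp(l0_i))`,
computed in log space. Degenerate priors are pinned: `p_i ∈ {0, 1}` forces
`e_i = p_i` exactly.

**M-step.** Maximize
`Q(beta) = sum_i [ e_i l1_i(beta) + (1 − e_i) l0_i(beta) ] − (lambda/2)|beta|^2`.
Both components are NB-GLMs in `beta`, so `Q` is maximized by IRLS on the
*stacked* two-component problem: rows are duplicated, the first copy using
`D'` with weight multiplier `e_i`, the second the condition-zeroed design
with multiplier `1 − e_i`. Each IRLS step solves

```
(A' W A + lambda I) beta_new = A' W z,
w = c / (1/mu + alpha),   z = h + (x − mu)/mu,
```

where `A` is the stacked design, `c` the stacked responsibilities, `h` the
current linear predictor and `mu = s·exp(h)` — the standard NB working
response and weights, one per component copy. Because IRLS is not globally
monotone, each step is backtracked (step-halving, up to 30 halvings) until
`Q` does not decrease; EM with an ascent M-step makes the penalized
observed-data objective `L` non-decreasing, which the test suite asserts to
1e−8 on every fitted instance.

**Why not fold the responsibilities into the working response?** A tempting
shortcut is a single-copy IRLS with `w = e/(1/mu + alpha)` and
`z = h + e(x − mu)/mu`. Its fixed point satisfies
`lambda beta = D'^T [ e^2 (x − mu) / (1 + alpha mu) ]`, which is **not** a
stationary point of `L` (or of `Q`) whenever some `e_i` is strictly between
0 and 1 — the inefficient component's contribution to the baseline gradient
is lost and the efficient component's is weighted `e^2` instead of `e`. The
stacked M-step above is the exact maximizer and coincides with the shortcut
when every `e_i = 1` (the default prior).

**Initialization and multi-start.** Baselines start at
`log(mean normalized count + 1)`, condition effects at 0. The mixture
likelihood is multimodal in the discrete efficient/inefficient assignment, so
when any prior is strictly inside (0, 1) EM is restarted from deterministic
responsibility corners — every 0/1 assignment for genes with ≤ 3 guides;
all-ones, all-zeros and each single-flip for larger genes — plus the
prior-seeded run, keeping the fit with the best penalized objective. A
2-guide counterexample motivates this: with one truly efficient and one
truly inefficient guide the global optimum lies at a mixed corner that
prior/all-ones/all-zeros starts miss by Δobjective ≈ 2.

**Convergence.** EM stops when `max |Δbeta| < 1e−4` (at most 100 iterations);
inner IRLS at `1e−6` (at most 50). A gene with all-zero counts is flagged
`estimable = False` and reported with zero coefficients. Linear predictors
are clipped to ±30 before exponentiation.

The test suite verifies the fitter end to end against an independent
Nelder–Mead maximizer of `L` on randomized small instances (agreement to
max |Δbeta| ≤ 1e−3; observed ≤ 1e−6).

## 5. Significance

**Wald.** At the optimum, with `W = diag(e_i / (1/mu_ij + alpha_i))` on the
efficient design, the coefficient covariance uses the ridge sandwich

```
Cov = (D'^T W D' + lambda I)^(−1) (D'^T W D') (D'^T W D' + lambda I)^(−1)
```

and `z_r = beta_r / se_r` is referred to the standard normal (two-sided). A
numerically zero SE with a zero coefficient reports p = 1.

**Permutation.** The null distribution of `beta_r` for a gene with `N` guides
comes from refitting pseudo-genes of size `N` whose guides are drawn without
replacement from the whole library, with the same size factors, dispersions
and priors. Draw count `B` defaults to `2 × (number of genes)`; pseudo-genes
are shared across all genes of the same size class. The two-sided add-one
rule `p = (1 + #{|beta_null| ≥ |beta_obs|}) / (1 + B)` keeps p-values in
`(0, 1]`. Draws are reproducible from `FitConfig.rng_seed`.

**FDR.** Benjamini–Hochberg within each condition, separately for Wald and
permutation p-values; NaNs propagate.

## 6. Quality control

Per sample: total reads, zero-count sgRNAs (count and fraction), Gini index
of `log2(count + 1)`, and — when FASTQ-level stats are available — mapped-read
percentage, GC-content histogram, per-position base-quality quartiles, and
median base quality. Across samples: Pearson correlations of
`log2(normalized count + 1)`, average-linkage clustering order on
`1 − r`, and a 3-component PCA of the samples (deterministic sign
convention: the largest-magnitude loading of each component is positive).

Default flag thresholds (each check reports pass/warn with the value and the
expectation):

| metric | expectation | applies to |
|---|---|---|
| mapped reads | ≥ 65% | all samples |
| mapped reads | ≥ 300 × n_sgRNA | all samples |
| median base quality | ≥ 25 | all samples |
| zero-count sgRNAs | ≤ 1% | all samples |
| Gini of log2 counts | ≤ 0.1 | plasmid / initial samples |
| Gini of log2 counts | ≤ 0.2 | selected samples |
| replicate correlation | ≥ 0.8 | declared replicate pairs |

The Gini index is computed by the sorted-vector identity
`G = 2 Σ_k k·v_(k) / (n Σ v) − (n + 1)/n` and equals the pairwise-difference
definition to 1e−12 (tested against an O(n²) oracle); it errors on all-zero
or negative input. A one-sided Mann–Whitney U test is provided for checking
that a known-essential gene set scores lower than the rest.

## 7. Read quantification

Counting is exact-substring matching of library spacers — no mismatches are
ever tolerated, by design (a single-mismatch read maps to nothing; this is
asserted exhaustively in the tests). Two trim modes: `fixed` (spacer expected
at a given offset) and `scan` (first match within `max_offset = 10` leading
positions; first hit wins). Optional reverse-complement matching. Gzipped
FASTQ is detected by suffix; qualities are Phred+33. Duplicate spacers in a
library are rejected up front because exact matching cannot disambiguate
them.

## 8. Simulator

`simulate_counts` draws per-guide baselines `beta_i0` log-uniform on
`[log 30, log 3000]`, assigns true condition effects (scalar → normal with
that SD; vector → round-robin across genes, same value in every condition;
matrix → exact per-gene/per-condition values), marks each guide inefficient
with a given probability, and draws NB (or Poisson when `alpha = 0`) counts
under the same mean model the fitter assumes. `default_design` builds one or
more all-zero baseline samples plus `conditions × replicates` selected
samples. `simulate_fastq` emits exactly `count_i` reads containing spacer
`i` (fixed 4-base prefix `ACCG`, read length 36, constant quality `I`),
optionally with junk reads verified not to contain any library spacer, in a
deterministic shuffled order.

Scope: the simulator matches the fitted model by construction (no GC bias,
no sample-specific dispersion, no guide-level off-target structure). It
validates recovery and calibration of the estimator, not robustness to model
misspecification.

## 9. Defaults

| parameter | default | rationale |
|---|---|---|
| `ridge_lambda` | 0.1 | weak shrinkage; keeps degenerate genes finite without visibly biasing \|beta\| ≤ ~2 |
| `max_em_iters` / `convergence_tol` | 100 / 1e−4 | beta changes below 1e−4 are far below reported SEs |
| `max_irls_iters` / `irls_tol` | 50 / 1e−6 | inner solve tighter than the outer loop |
| `dispersion_prefit_alpha` | 0.01 | mild NB prefit; results insensitive to ±1 order of magnitude |
| `alpha_floor` | 1e−6 | avoids exactly-Poisson weights and division issues |
| `n_permutations` | `"auto"` = 2 × genes | resolution ~1/(2·genes), adequate for BH at gene-level FDR |
| prior efficiency | 1.0 | without scores, every guide assumed active (mixture off) |
| trim `max_offset` | 10 | typical vector prefixes; scan stops at first hit |
| linear-predictor clip | ±30 | exp(30) ≈ 1e13 caps mu without touching realistic fits |

## 10. Limitations

- **Wald small-sample behaviour.** With few samples (e.g. 3) the Wald test is
  slightly liberal: the type-I rate at p < 0.05 over 2000 null genes is about
  0.07–0.09 across seeds. The permutation p-values are uniform
  (KS distance to U(0,1) ≈ 0.01–0.02) and should be preferred for calibrated
  inference in small designs.
- **Dispersion at the Poisson limit** is bounded away from zero (~3e−4, see
  §3); this is immaterial for fitting since such alphas are negligible at
  screen-scale counts.
- **Exact matching only:** sequencing errors inside the spacer drop reads
  rather than miscounting them; deep screens tolerate this, shallow ones lose
  a few percent of reads.
- Conditions are binary indicators; continuous covariates and batch terms are
  not modelled.
- Permutation nulls are shared within a gene-size class (a compute/precision
  trade-off); per-gene exclusive nulls would cost `genes ×` more fits.
- The efficiency mixture needs an informative contrast: with a single sample
  per condition and weak effects, efficient and inefficient explanations are
  near-equivalent and the posterior stays near its prior.
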