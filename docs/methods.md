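# Statistical methods

This note describes the models, estimators and numerical choices behind each
module. Notation: genes are indexed by *g*, samples by *s*; the eight
tissue × treatment combinations (`Mz/Ez/Co/St` × `control/deficit`) are
called *cells* and indexed by *c(s)*; counts are `y_gs`.

## 1. Generative model and the synthetic-data generator

Counts are negative binomial with a natural-log link:

```
y_gs ~ NB(mu_gs, phi_g)          Var = mu (1 + phi mu)
log mu_gs = o_gs + beta_{g,c(s)} + u_{lane(s)} + v_{rep(s)}
```

- `o_gs` is a known offset: log(effective library size / 1e6) plus a
  per-gene length/GC term, so `beta` lives on the log reads-per-million
  (log-RPM) scale.
- `beta_{g,c} ~ N(m_c, s2_c)` independently per cell (diagonal population).
- `log phi_g ~ N(d, t2)`.
- Lane effects `u ~ N(0, 1/tau_u)` and replicate effects `v ~ N(0, 1/tau_v)`
  are shared across genes within a sample; their precisions carry gamma
  populations.

`rootzone.simulate` draws from exactly this model. Defaults
(`SimulationConfig`) emulate a desk-scale study: 1000 genes, 4 replicates,
8 libraries multiplexed as 4 per lane, `m_c = log 15` RPM, `s2_c = 2.25`,
`log phi ~ N(log 0.1, 0.25)`, mean library size 1e6 with 0.15 log-sd. A
`fraction_inactive = 0.3` of genes has a random subset of cells forced to
`log 0.05` RPM (a well-separated "off" state), and `fraction_de = 0.1`
carries planted ±2 log2 treatment effects for DE validation. Ground truth
(`truly_active` at the `log 2` RPM generation threshold, planted fold
changes, realized lane/replicate effects, realized library sizes and the
generation-time offsets) is retained on the returned objects for
estimator-recovery tests.

Covariate bias: expected counts are multiplied by
`exp(1.0 · log-length + (−2.0) · GC²)` on centred covariates — a smooth,
non-linear surface the normalization smoother must recover.

Determinism: every stochastic routine takes a seed; `simulate_counts`
accepts an explicit `seed` that overrides the config-derived default.

## 2. Normalization

**TMM factors** (`tmm_factors`): the classical trimmed-mean-of-M-values
estimator. For each sample against a reference column (the one whose
upper-quartile CPM is closest to the mean), genes with positive counts in
both columns contribute M (log2 ratio) and A (average log2 abundance)
values; the top/bottom 30% by M and 5% by A are trimmed; the remaining M
values are averaged with delta-method inverse-variance weights
`(1/y1 − 1/N1 + 1/y2 − 1/N2)^-1`; factors are exponentiated and rescaled to
unit geometric mean. Because the precision weights depend on absolute
counts, the factors are depth-invariant only approximately (relative
changes ~1e-3 under 8× depth scaling); tests assert invariance at rtol
5e-3, not machine precision.

**Covariate smoother** (`fit_covariate_smoother`): a 2-D local-linear
regression of per-gene mean log CPM on (GC fraction, log length), with
tricube weights on standardized covariate distances and a span of 0.5. The
fitted surface is centred (mean zero across genes) so it redistributes,
rather than rescales, the offsets. Requires ≥ 50 genes and non-constant
covariates.

**Composition** (`compose_offsets` / `normalize`):
`o_gs = smoother_g + log(TMM_s · N_s / 1e6)`. The `library_sizes`
convention matters: `normalize()` defaults `N_s` to column sums, which is
correct only when the matrix covers (essentially) the whole transcriptome.
When the counts are a subset — as in the simulator, where the realized
mapped totals are known — pass the true totals via `library_sizes=`;
the acceptance script and the worked examples do so. Offsets are only
identified up to a per-sample constant against the model's intercepts, so
recovery tests compare centred offsets.

## 3. Activity model

### Hyperparameter estimation (`estimate_hyperparameters`)

Empirical Bayes, method of moments:

1. Per-gene, per-cell MLEs of `beta` at a working dispersion, with
   `sample_residual_adjustment` first added to the offsets: the lane and
   replicate effects (and any residual error in the TMM factors) are shared
   across genes, so the median across well-expressed genes of the
   per-sample log-count residual estimates their sum; adding it to the
   offsets approximates profiling the sample effects out of each per-gene
   likelihood, removing a bias in the moment estimates of `s2_c`.
2. Genes whose fitted `|beta|` hits the ±14 log-RPM identifiability bound
   (all-zero cells and similar) are dropped from the moment estimates
   (`n_dropped` is recorded); the population therefore describes the
   *expressed* component, which is what the activity prior should shrink
   toward.
3. `m_c`, `s2_c` from trimmed moments of the retained MLEs with a
   curvature-based subtraction of estimation noise.
4. Per-gene dispersions by Cox–Reid adjusted profile likelihood on a
   `log phi` grid; `d`, `t2` from their moments, again noise-corrected.
5. Lane/replicate effect variances by least-squares decomposition of
   per-sample mean residuals on the lane and replicate factors; the
   gamma populations for the precisions are set vague-by-default
   (`lane shape/rate = 0.01/0.01`, i.e. prior mean 1 with huge variance)
   unless the decomposition is informative. Note this deviates from the
   generator, which draws tight lane precisions (shape 50, rate 0.5) —
   the analysis model deliberately does not assume lanes are as quiet as
   the generator makes them.

### Per-gene posteriors (`fit_posteriors` / `_laplace_gene`)

A nested Laplace scheme per gene:

- **Plug-in precisions.** The random-effect precisions `tau_u`, `tau_v`
  enter at their empirical-Bayes gamma-prior means rather than being
  maximized jointly: the joint mode over effects *and* precisions is
  degenerate (the "funnel" — a precision can run to infinity while its
  effects collapse to zero, or vice versa), so plugging in the prior mean
  is both stabler and closer to the integrated posterior.
- **Plug-in dispersion.** Each gene's `phi` is its Cox–Reid estimate shrunk
  toward the population (`log phi` posterior mean under the normal
  population with curvature-weighted likelihood). Oracle tests of the
  Laplace machinery must therefore use the *same* plug-in `phi` on both
  sides; comparing against the generating dispersion confounds
  approximation error with dispersion-estimation error.
- **Joint mode.** Damped Newton ascent with backtracking line search on the
  joint log posterior of (8 betas, lane effects, replicate effects) with
  independent normal priors (`N(m_c, s2_c)` on betas, `N(0, 1/tau)` on
  random effects).
- **Marginal refinement.** The Gaussian-at-the-mode marginal is poor at low
  counts (the NB log likelihood in `beta` is strongly left-skewed when few
  reads are observed). Each cell's marginal is refined by 1-D numerical
  integration of its conditional posterior along a 321-point grid spanning
  ±8 marginal sds at the joint mode, yielding (mean, variance, skewness);
  the variance is then inflated by the marginal/conditional curvature
  ratio from the joint Hessian so the uncertainty of the integrated-out
  random effects is retained. The three moments are summarized as a
  moment-matched skew-normal (delta capped at |δ| ≤ 0.995, beyond which
  the moment map is non-invertible).

Against a dense 40,001-point quadrature oracle at shared plug-in `phi`,
the worst absolute error of `P(beta > T)` across 100 random single-replicate
instances is ≈ 0.002 (tested at ≤ 0.02).

### Calls and threshold calibration

A gene is **active** in a cell iff `P(beta_{g,c} > T) > 0.5` *strictly*
(`p = 0.5` exactly is inactive — the boundary pseudo-gene is on the
inactive side). `T` is calibrated (`calibrate_threshold`) so that an
average pseudo-gene — population-mean prior, population-mean dispersion,
zero smoother term — observed at exactly its expected count
(`target_rpm · N/1e6`, default 2 RPM in a 1e6-read library) in each of the
`n_replicates` libraries of one cell sits exactly on the boundary: its
posterior is computed by the same mode + 1-D-refinement scheme, and `T`
solves `sn_sf(T) = 0.5` by Brent's method (xtol 1e-10). `boundary_rpm`
inverts the map (root-find over log RPM), which closes the loop to the
target within ~1e-12 relative error; `boundary_count` rescales for a
non-average gene via its smoother term.

## 4. Activity-pattern taxonomy

Each gene reduces to the pair (set of tissues active under control, set
active under deficit); the number of **changes** is the symmetric-difference
size. Categories (a full partition, in precedence order): `never_active`
(both sets empty), `constitutive_all` (both sets all four tissues),
`stable_single` / `stable_multi` (identical non-empty sets, one vs several
tissues), `dynamic_increase` (control set a strict subset of deficit set),
`dynamic_decrease` (strict superset), `dynamic_change` (any other unequal
pair). `tabulate_patterns` reports category counts, the change-count
distribution among dynamic genes, per-tissue × condition active counts and
16-subset Venn occupancies per condition, with shares computed over active
genes (i.e. excluding `never_active`).

## 5. Differential expression

Deficit-vs-control contrasts per tissue on `log2 CPM` with precision
weights (a voom-style pipeline):

1. **Filter** (`filter_expressed`): keep genes whose max cell-mean count
   ≥ `min_count` (default 5).
2. **Transform and weight** (`transform_and_weight`):
   `log2((y + 0.5) / (N_s · TMM_s / 1e6))`; a lowess trend of sqrt
   residual-sd on average log count gives per-observation weights
   `pred^-4` (trend floored at 1e-3 and NaN-guarded for degenerate
   inputs).
3. **Lane-block correlation** (`estimate_block_correlation`): per-gene
   within-lane residual correlations combined by a Fisher-z consensus; the
   single scalar `rho` induces a compound-symmetry covariance per lane
   block.
4. **Weighted GLS** (`fit_contrasts`): per gene, whiten by the block
   correlation, regress on the 8 cell indicators, and report the 4
   treatment contrasts with standard errors and residual df (24 for a
   4-replicate design).
5. **Moderation** (`moderate_and_test`): limma-style empirical Bayes —
   the prior df `d0` and prior variance `s0²` solve the marginal moments of
   log residual variances via trigamma inversion; moderated variances
   `(d0 s0² + d s²)/(d0 + d)`, t-tests on `d0 + d` df. `prior_df = 0`
   reproduces classical per-gene t-tests; `prior_df = inf` uses the prior
   variance alone.
6. **FDR** (`adjust_fdr`): Benjamini–Hochberg via
   `statsmodels.stats.multitest.multipletests`, validated against a
   step-up loop oracle.
7. **Responsive-gene summary** (`select_responsive`): per-tissue and
   any-tissue hit counts at (FDR, |log2FC|) cuts, multi-tissue counts, and
   direction-consistency among multi-tissue responders.

**Known limitation — low-count conservatism.** The log-CPM + weights
approximation is conservative for genes with mean counts below ~30: under a
true null their p-values pile up near 1 (the discreteness and the
mean–variance mismatch of the log transform are not fully absorbed by the
weights), so a mixed-abundance null population fails a strict
uniformity (KS) test even though the test never becomes anti-conservative.
Calibration claims — null p-value uniformity and FDR control — therefore
hold for *expressed* genes (the simulation probes use an expressed-only
population); for weakly expressed genes the test loses power but does not
inflate false positives. Count-based models (exact NB tests) would be
needed below that regime.

## 6. Enrichment

**Category enrichment** (Fisher): for each annotation category within each
annotation system, a one-sided hypergeometric upper tail
(`scipy.stats.hypergeom.sf(k−1, M, n, N)`) of the overlap between
responsive genes and the category, over the *annotated background only*
(genes absent from the annotation are excluded from `M`, `n` and `N`);
duplicate gene–category rows collapse to one membership. BH across
categories within a system.

**Pattern-composition test** (chi-square): responsive-gene counts across
the activity-pattern categories against expectations proportional to the
full gene population's composition. Categories come from the full
partition (so empty-in-background categories are representable); any
category with expected count < 5 is merged into `other` (with a warning)
before `scipy.stats.chisquare`, df = k − 1. A responsive set with no
annotated/patterned member raises rather than returning a vacuous test.
Null calibration: ~5% rejections at alpha 0.05 over random subsets.

## 7. Diagnostics

Sample distances are root-mean-square differences of log2 CPM over the
top-`k` genes by leading variability (per-pair, largest `k` squared
differences — the "leading fold change" convention, `k` clamped to the gene
count with a warning); average-linkage agglomeration yields a Newick tree,
and classical MDS (Torgerson double-centring + eigendecomposition) yields
2-D coordinates. On simulated data, same-tissue samples are closer than
different-tissue samples, and planar configurations are reproduced exactly.

## 8. Pipeline

`run_pipeline` executes `normalize → activity → patterns → de → enrich →
qc` (enrich skipped without an annotation; any subset of stages can be
requested, but each stage validates that its upstream products exist and a
missing dependency fails with the stage name in the error and in the
manifest). All outputs are TSV/JSON text with fixed float formatting;
reruns on identical inputs are byte-identical. `manifest.json` records
SHA-256 hashes of all inputs, every parameter, the calibrated threshold
and the completed-stage list.

## 9. Validation strategy

Every component is tested against an independent oracle: loop-based TMM
with explicit trimming bookkeeping; dense-grid posterior quadrature at
shared plug-in dispersion; an exhaustive 256-pair enumeration of the
pattern taxonomy; `comb`-based hypergeometric tails; a step-up BH loop;
`scipy.stats.chisquare`; brute-force leading-fold-change distances — plus
simulation-based recovery checks (hyperparameters within 20% relative
error at 5000 genes; activity sensitivity and specificity ≥ 0.95 on
well-separated populations; DE null KS-uniform on expressed genes and
empirical FDR ≤ 2× nominal on planted effects).
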