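# Methods

## Model

Phenotypes are modeled as y_i = β₀ + Σⱼ x_ij βⱼ + ε_i, with x_ij the dosage
of marker j in line i and ε_i mean-zero noise independent of the markers.
With p ≫ n the coefficients are estimated by ridge regression,

PRSS_λ(β) = (y − β₀1 − Xβ)ᵀ(y − β₀1 − Xβ) + λ Σ_{j=1..p} βⱼ²,  λ ≥ 0,

on exactly this λ scale (no 1/(2n) factor). The intercept is never
penalized: solvers center y and the columns of X, estimate β on the
centered data, and set β₀ = ȳ − x̄ᵀβ̂, so predictions on raw X equal the
internal centered computation identically. Predictors are *not* rescaled
inside the solvers — the penalty applies to coefficients on the original
dosage scale, which is what makes proxy coefficients transferable to the
goal design without a basis change.

Two solver pathways minimize the same objective and are cross-checked
against each other (1e-6) in the tests:

* **analytic** — the penalized normal equations, solved primal
  ((XᵀX+λI)⁻¹Xᵀy, p ≤ n) or dual (Xᵀ(XXᵀ+λI)⁻¹y, p > n) so cost scales
  with min(n,p)³. λ = 0 is allowed only for full-column-rank centered
  designs (then it is OLS); otherwise the error advises a positive λ.
* **iterative** — cyclic coordinate descent on the centered columns.
  The coordinate update βⱼ ← xⱼᵀr₋ⱼ/(xⱼᵀxⱼ+λ) needs no standardization to
  target the identical objective, so none is applied and no back-transform
  is needed. Convergence is declared when the largest absolute coefficient
  change in a sweep falls below `tol` (default 1e-10); non-convergence
  raises, carrying the last iterate. The inner loop is JIT-compiled
  (numba), with an interpreted fallback.

Keeping both pathways mirrors the field's habit of comparing a
library-optimized ridge against the closed form. Because both are driven to
tight tolerance on the same objective here, their accuracy metrics usually
agree to print precision; published RR-vs-ARR gaps stem from differing
λ parameterizations between implementations, which this package
deliberately avoids.

## Transfer estimator

Given a fully phenotyped proxy environment and a partially phenotyped goal
environment measured on the same markers:

1. β̂_p = ridge fit on the complete proxy data, λ_p tuned by inner CV on
   the proxy;
2. y\* = y_g − (β̂₀ₚ + X_g β̂_p) on the goal training subset;
3. γ̂ = ridge fit of y\* on X_g, λ_g tuned by inner CV on the goal training
   subset with the adjusted response;
4. β̂_g = β̂_p + γ̂ (intercepts added likewise);
5. goal-test predictions use β̂_g.

λ_p and λ_g are tuned independently by the same inner-CV procedure — the
only self-consistent choice given that the two stages see different data.
The proxy intercept is carried into y\*; since the γ stage centers its
response, predictions are provably invariant to this choice (verified in
tests), and carrying it keeps y\* free of the proxy-mean shift.

Two exact identities anchor the implementation: β̂_p = 0 reduces the
transfer fit to plain ridge on the goal training data, and λ_g → ∞ drives
γ̂ → 0 so predictions collapse onto the proxy model re-shifted to the
goal-train mean (equal to raw proxy predictions exactly when the proxy fit
is mean-unbiased on the goal training rows — the tests construct this case
explicitly). The γ stage always recentering is what makes the reduction
identity exact; the mean shift in the opposite limit is the price, and in
practice it is a correction one wants.

Lines present in both the proxy data and a goal test split are retained by
default — fully shared panels make this unavoidable and the protocol treats
the proxy fit as prior information, not as training on the test response.
Strict separation is available by subsetting the proxy design before
fitting. One proxy environment per transfer; multi-proxy weighting is out
of scope.

## Hyperparameter tuning

Candidate λ values form a log-uniform grid anchored at
a = max_j |x̃ⱼᵀ(y−ȳ)| computed on unit-variance columns. Ridge has no
finite λ at which coefficients vanish, so the grid runs from a×10³ down to
a×10³×min_ratio (defaults: 100 points, min_ratio 1e-6 ≈ nine decades). The
wide span matters: low-noise designs place the MSE optimum near the
unpenalized end, and a narrower span (e.g. min_ratio 1e-4) demonstrably
truncates it. The anchor scales linearly with y, making the grid
scale-equivariant.

λ* minimizes the mean validation MSE over 10 seeded random 80/20 inner
splits of the training data; only inner-training rows ever enter a fit.
Ties — exact to relative machine precision, as with duplicated grid
values — resolve to the larger λ (stronger regularization). Splits whose
inner-training response is constant are skipped with a warning and the
averaging denominator adjusted. Zero-variance columns within a split
receive coefficient 0.

For the analytic pathway the whole λ path of one split is evaluated through
one eigendecomposition of the centered training Gram matrix (dual form),
with the design's Gram computed once and split Grams obtained as centered
submatrices — algebraically identical to refitting per λ (tested to 1e-8)
but roughly two orders of magnitude faster. For the iterative pathway the
path is traversed from large to small λ with warm starts; scoring fits use
a looser, capped convergence criterion (tol 1e-6, ≤300 sweeps), as
library implementations do, while final fits use the strict criterion.

## Evaluation protocol

Outer evaluation uses 10 independent random 80/20 partitions of the goal
lines (|train| = round(0.8·n); independent draws, not disjoint folds).
Per partition, conventional models are tuned and fitted on the training
split alone; transfer models reuse the same split plus the proxy
coefficients, whose fit does not depend on the partition and is computed
once. Inner CV is re-run per partition. Metrics on the test split:

* **Cor** — sample Pearson correlation, flagged undefined (NaN) when either
  side has zero variance; undefined cells are excluded from averages and
  counted, never coerced to 0;
* **NRMSE** — RMSE divided by |mean| of the observed test values (the
  common convention in this literature; `range` and `sd` normalizers are
  available behind the same flag). The NRMSE *level* therefore depends on
  where the trait mean sits; only comparisons between models on the same
  data are meaningful.

Aggregation gives every trait × pair × partition cell equal weight; SDs are
sample SDs. Relative efficiencies compare model-side averages:
(AvgCor_T/AvgCor_C − 1)×100 and (AvgNRMSE_C/AvgNRMSE_T − 1)×100, so
positive values always mean transfer helped. Determinism: outer partition
k draws with seed+k, inner CV within partition k with seed+10000+k, the
proxy tuning with seed+20000; identical seeds reproduce results
bit-for-bit.

## Synthetic data

The generator emulates multi-environment trial structure: n lines × p
independent biallelic markers (allele frequency uniform on `maf_range`,
dosage Binomial(2, f) — no linkage disequilibrium, which the estimator
identities under test do not need), two environments sharing a configurable
fraction of lines (the first round(f·n) lines in panel order; the remainder
alternate proxy/goal), and per-environment phenotypes y = base + Xβ_env + ε.
Marker effects at causal positions are bivariate standard normal across
environments with correlation ρ — the single dial standing in for
environmental relatedness. Noise variance solves
var(Xβ)/var(y) = h² against the realized genetic variance per environment;
realized h² is recorded. The trait mean `base_value` (default 20, arbitrary
units) keeps mean-normalized NRMSE away from a near-zero denominator, as
for real traits; Cor and all model contrasts are invariant to it.

The reference study condition is 480 lines, 1000 markers, shared fraction
2/3 (each environment then holds 400 lines; outer 80/20 gives 320 training
and 80 test lines), all markers causal (a fully polygenic architecture —
the regime ridge assumes), h² = 0.5 in both environments, ρ ∈ {0, 0.9},
30 replicates, ARR vs Transfer_ARR. At ρ = 0.9 the transfer gain is large
and significant under a paired one-sided t-test; at ρ = 0 there is no
systematic gain and negative transfer appears — the qualitative law that
relatedness drives transfer benefit. The iterative pathway is excluded from
this Monte-Carlo condition only for compute: it adds no information, since
the two pathways agree to print precision (see above).

What passing these simulations does *not* show about real data: markers
here are in linkage equilibrium, effects are homogeneous-variance normal,
environments differ only through effect correlation and noise, and line
overlap carries no population structure. Real datasets confound
relatedness, panel overlap and sample size; the generator deliberately
decouples them.

## Data handling

Genotypes are delimited text (marker-id header, line-id first column;
configurable missing token, default `NA`); phenotypes are long-format
records (line, environment, trait, value) — records rather than matrices,
because environments share only some lines. Matching is exact string
equality after whitespace trimming; duplicate identifiers and conflicting
duplicate records are hard errors; blank phenotype values are dropped and
counted. Missing dosages are column-mean imputed on demand; aligning an
unimputed matrix is an error rather than a silent fix. Alignment intersects
genotyped and phenotyped lines in marker-matrix row order, so shared lines
receive identical X rows in every environment's design. Output floats are
written at 6 significant digits.

## Known limitations

Single trait, single proxy; no kinship/GBLUP parameterization, no
MAF/call-rate quality control, no LD or epistasis in the generator; NRMSE
levels are only comparable within a dataset; the iterative pathway's tuning
MSEs are approximate at the extreme low-λ end of the grid by design
(capped sweeps), which can matter only when the MSE curve is still falling
there — i.e. in near-noiseless data.
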