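# Methods

## Scope and model

`gsabench` addresses two linked questions about transcriptomic gene-set
analysis. First, whether the p-dimensional expression vector of a gene set
follows a multivariate normal (MVN) distribution — the implicit assumption
behind much FCS-GSA benchmarking. Second, how the type-I error and power of
eight self-contained gene-set association tests respond when that assumption
fails in the ways real data fail it: heavy tails and sub-population
(disease-subtype) mixtures.

All simulated populations are finite mixtures of multivariate normal and
multivariate Student-t components. The Student-t components use the *scale*
parameterisation MVT(μ, Σ, ν): the covariance is ν/(ν−2)·Σ for ν > 2, so
MVT₃(0, Σ) has covariance 3Σ. This matches the convention of the standard R
generators and keeps the written designs reproducible across toolchains.
Mixture draws use per-row component indicators (weights are probabilities,
not quotas), so a sample of n rows from a 0.5/0.5 mixture contains a
Binomial(n, 0.5) number of rows from each component.

## The MVN tests

All six statistics act on the Mahalanobis-standardised sample
z_i = S^{−1/2}(x_i − x̄) with S the maximum-likelihood covariance and
S^{−1/2} the symmetric eigendecomposition root (eigenvalues below
10⁻¹²·tr(S) are refused as singular rather than floored — the protocols are
designed so the covariance stays invertible, and a silent pseudo-inverse
would change the tests' meaning).

* **Mardia**: b₁,ₚ = n⁻²Σᵢⱼ(zᵢ'zⱼ)³ and b₂,ₚ = n⁻¹Σᵢ‖zᵢ‖⁴. Skewness refers
  n·b₁,ₚ/6 to χ² with p(p+1)(p+2)/6 df; kurtosis compares b₂,ₚ with p(p+2)
  via a two-sided normal z. The decision rule rejects when *either*
  component reaches α, and the reported p-value is min(p_skew, p_kurt).
  This is a **union rule**: with both components calibrated its null level
  is 1−(1−α)² ≈ 0.0975 at α = 0.05, not α. The package reports it faithfully
  and documents the consequence (see *Calibration*, below). `correction=True`
  swaps in Mardia's exact finite-sample moments for both components — at
  n = 50, p = 10 the asymptotic kurtosis z has null mean ≈ −1.07 and
  sd ≈ 0.70, so the asymptotic component alone rejects ~10%; the exact
  moments restore component-level calibration. The default is the
  asymptotic (textbook) form.
* **Henze–Zirkler**: the weighted L2 distance between characteristic
  functions with bandwidth β(n,p) = ((n(2p+1))/4)^{1/(p+4)}/√2; the p-value
  uses the classical lognormal approximation to the null (a Monte-Carlo null
  is available).
* **Royston**: per-coordinate Shapiro–Wilk W, normalised to z-scores
  (Royston's 1992 transformation, valid for 4 ≤ n ≤ 2000), folded into 1-df
  χ² contributions and combined with correlation-adjusted equivalent degrees
  of freedom e ∈ [1, p]; at p = 1 it reduces exactly to the univariate SW
  test.
* **FA**: project the standardised sample onto each observation's own
  direction zᵢ/‖zᵢ‖ and take the minimum SW W over directions; small W
  rejects.
* **TN**: the mean SW deficiency (1/p)Σⱼ(1−Wⱼ) over the standardised
  coordinates; large T rejects. The exact combination used by the original
  authors is not published in the sources available here; this form is a
  documented stand-in isolated in one function (`_tn_statistic`) so it can
  be swapped without touching any protocol code.
* **Energy**: the one-sample energy distance between the standardised sample
  and N(0, I_p), with E‖Z−Z′‖ = 2Γ((p+1)/2)/Γ(p/2) and E‖a−Z‖ evaluated via
  the confluent-hypergeometric closed form ₁F₁(−½; p/2; −‖a‖²/2).

FA, TN and Energy take Monte-Carlo nulls from standardised N(0, I_p) draws
(B = 499 by default, 199 inside the protocols), valid because the statistics
are distribution-free under the null after standardisation. Nulls are
regenerated per call rather than cached: sharing one null sample across
protocol replications would correlate their rejection events and inflate the
variance of the rejection rate Q around α. A batched Shapiro–Wilk (AS R94
weights, checked against `scipy.stats.shapiro`) keeps this affordable —
an FA call evaluates n·(B+1) SW statistics.

Invariance: Mardia, HZ, FA and Energy are exactly affine invariant. Royston
is invariant to per-coordinate monotone-linear maps only (coordinate-wise SW
is not rotation invariant), and TN's standardised coordinates are defined up
to an orthogonal rotation — both are invariant *in null distribution*, which
is what the Monte-Carlo null requires.

## The GSA tests

Labels are 0 = control, 1 = case; X is samples × genes restricted to one
set; permutation and rotation p-values use (b+1)/(B+1); every permutation
test can enumerate all C(n, n₂) label assignments exactly when affordable.

* **Global test**: Q = (Y−ȳ)'XX'(Y−ȳ)/m on column-centred X; label
  permutation (B = 999 standalone, 199 in benchmarks) rather than the
  asymptotic null — exact at any n with no extra assumptions.
* **Hotelling T²**: classical pooled-covariance form with the exact
  F(p, n₁+n₂−p−1) reference whenever n₁+n₂−2 > p (always true in the
  benchmark designs); otherwise a Ledoit–Wolf-shrunk covariance with a
  permutation null.
* **Rotation / moderated-t (ROAST-style)**: each gene's two-group linear
  model is reduced by the QR decomposition of the design to one effect
  coordinate plus d = n−2 residual coordinates; residual variances are
  shrunk toward a prior fitted to all set genes by the standard
  F-distribution moment match (solved with a trigamma Newton inversion);
  moderated t (df d+d₀) maps to z; the set statistic is mean(z), two-sided
  (mean(z²) available). The null redraws the effect direction uniformly on
  the unit sphere of the (d+1)-dimensional reduced space — a rotation, which
  preserves inter-gene correlation exactly. The prior (d₀, s₀²) is estimated
  once from the observed data and reused across rotations, matching the
  established implementation of this test.
* **Pathway activity score**: per-gene ranks across all samples; gene
  weights = mean |Pearson correlation| with the other set genes; per-sample
  score = weighted mean rank; 1-df likelihood-ratio test of the score in a
  logistic regression of the label. The published score's exact form is not
  in the sources available here; this construction is a documented stand-in
  isolated in `pscore_test`. Perfect separation falls back to the saturated
  LRT bound with a note in the result.
* **Self-contained GSEA**: set statistic Σ_g t_g (pooled-variance two-sample
  t per gene; zero-variance genes contribute 0), two-sided label-permutation
  null. This is deliberately the self-contained sum-of-t modification, not
  the competitive weighted running-sum enrichment score.
* **N-statistic**: the two-sample Euclidean energy distance between case and
  control samples; label permutation over the precomputed pooled distance
  matrix.
* **MST Kolmogorov–Smirnov (mean / variance)**: pool the samples, rank them
  one-dimensionally, and take D = max over prefixes of |F̂₁ − F̂₂|. The
  location ranking builds the Euclidean minimum spanning tree (Kruskal with
  stable index-order tie-breaks), roots it at a node of maximum hop
  eccentricity (smallest index on ties) and emits the high-directed-preorder
  DFS, visiting children in decreasing subtree size; the scale ranking
  orders points by distance from the pooled centroid. The exact traversal of
  the original implementation is not published in the sources used here;
  root choice and child ordering are therefore fixed, documented and
  isolated in `mst_hdp_ranks`. Labels permute over the *fixed* pooled
  ranking — the ranking is label-independent — which makes B = 999
  affordable. D is discrete (multiples of 1/n₁ ∧ 1/n₂), so the permutation
  p-values are conservative at small n and only approximately uniform at
  n = 50 per group.

## Protocols

**Rejection-rate protocol.** For a cohort of n samples the subset size is 10
genes if n > 30 and 5 otherwise, so that n comfortably exceeds the subset
dimension and S is invertible. Each of n_reps (default 1000) replications
draws a subset without replacement from the gene set, runs one MVN test and
records p; Q = #{p ≤ α}/n_reps. Replications that fail (singular S) are
excluded from the denominator and counted in the summary — silently keeping
them would bias Q.

**Power study.** For each (design, Δ) cell, every replication generates a
fresh two-group dataset (50 + 50 by default, p = 30) and runs *all*
requested tests on it — a paired design that makes cross-test comparisons
sharper at fixed cost. Rows at Δ = 0 estimate the type-I error; each cell
reports power, the replication count and the binomial Monte-Carlo standard
error. Inner resampling defaults to 199 in benchmark context and 999 for
standalone runs.

**KL distance from normality.** KL(P‖Q) is estimated from samples by the
kNN estimator (p/n)Σᵢ log(ν_k(i)/ρ_k(i)) + log(m/(n−1)); per design the
summary is KL(case‖N(0,I)) + KL(control‖N(0,I)). The mean shift and sample
size behind the summary are free parameters (defaults Δ = 0.5 — the grid
midpoint — n = 10000, k = 5), so the table is interpreted as an *ordering*
(every heavy-tailed design diverges further than its matched normal design),
never as absolute values. Finite-sample notes: the estimator can be
negative; in moderate dimension it carries an O(10%) negative bias at
k = 5, m = n (shared by reference implementations); k = 1 and a larger
reference sample m reduce it, which is how the closed-form Gaussian recovery
check is configured. Points of the reference sample at exactly zero distance
from a query are treated as self-matches and skipped, keeping the estimator
finite when the samples share points.

## Seeding and determinism

One master seed drives everything. Substreams are addressed through
`numpy.random.SeedSequence` spawn keys (per replication, per method), so any
single replication can be re-run in isolation and every protocol output is a
pure function of (seed, parameters). Derived integer seeds stay below 2³¹.

## Synthetic expression data

`generate_expression_dataset` emulates what the protocols need from real
expression matrices: genes × samples orientation, named gene sets whose
members are correlated (compound symmetry, ρ = 0.1 by default) and may carry
any design A–H group structure, i.i.d. background genes, and optional
lognormal or Student-t marginals as constructed normality violations. It
does **not** model platform effects, library-size normalisation, count
noise, or single-cell dropout beyond sparse zeros — passing tests on these
datasets validate the machinery and its calibration, not any claim about a
particular real cohort.

## Calibration expectations and known limitations

* The five tests whose reported p-value is a genuine p-value (HZ, Royston,
  FA, TN, Energy) hold the 99% binomial band around α = 0.05 on null data at
  the protocol scale (n = 50, p = 10, 1000 replications). The Mardia
  *decision rule* cannot: the either-or union of two 5% components has level
  ≈ 0.0975 even when both are calibrated, and ≈ 0.11 with the asymptotic
  kurtosis moments at this n and p. This is a property of the published
  decision rule, reproduced deliberately; use `correction=True` and the
  component p-values when component-level calibration matters.
* All eight GSA tests hold their level under design A; the two MST-KS tests
  are conservative at small group sizes (discrete D).
* Quantile normalisation equalises column multisets exactly only in the
  absence of ties; tie groups receive the mean of the reference values they
  span.
* The rejection-rate protocol on real cohorts (GEO/TCGA/Single-Cell-Portal
  accessions) is supported through the TSV/MTX/GMT readers, quantile
  normalisation and the top-variable-gene filter, but no downloading client
  is included and no real-data results are asserted anywhere in the test
  suite.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` runs each power/type-I cell at 500 replications with
199 inner resamples and the MVN calibration at 1000 replications — sizes
chosen so the Monte-Carlo standard error (≈ 0.01 on a proportion near 0.05,
≈ 0.022 near 0.5) is small relative to the effects being demonstrated, while
the whole script completes in minutes on a single CPU.
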