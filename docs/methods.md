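# Methods

## Model

Relative transcript expression is a point `x` on the open unit simplex
`Δ^{n−1}`.  Each transcript `j` induces a distribution `p_j(·)` over
possible reads; the data enter only through the sparse matrix of
conditional probabilities `p_j(r_i)` (here treated as given — fragment
models and sequence-bias corrections happen upstream of this package).
The likelihood is the sparse mixture

    P(r | x) = ∏_{i=1}^{m} Σ_{j=1}^{n} x_j p_j(r_i).

Identical rows are collapsed into equivalence classes with integer
multiplicities; this is exact because the likelihood factors over rows.
The *normalized likelihood* — the likelihood rescaled to integrate to 1
over the simplex, equivalently the posterior under a uniform Dirichlet
prior — is the object every component of this package targets:

- **Gibbs reference.** A data-augmented sampler alternates read
  assignments `z_i | x` (categorical over the row support) with
  `x | z ~ Dirichlet(1 + counts)`.  Defaults: 8 independently initialized
  chains, 2000 burn-in iterations, 25000 sampling iterations with every
  25th draw kept (1000 per chain).  Convergence is monitored with
  split-chain potential scale reduction.  The inner loop is a numba
  kernel; a multinomial row split is drawn as a chain of binomials.
- **EM point estimate.** The classic fixed-point update
  `x_j ∝ Σ_i w_i x_j p_j(r_i) / Σ_k x_k p_k(r_i)` from a uniform start,
  tolerance 1e-9 on the max component change, ≤1000 iterations.  Used for
  initialization and as the point-estimate baseline in comparisons.

## The Pólya tree transformation

A full binary tree with `n` leaves (root labeled 1, internal nodes
`1…n−1`, leaves `n…2n−1`, children always labeled above parents) turns
break fractions `y ∈ (0,1)^{n−1}` plus a stick length `u1` into `n`
positive pieces: `u_left(i) = y_i u_i`, `u_right(i) = (1−y_i) u_i`, with
leaf values read out through an explicit leaf→transcript permutation.
The map is a bijection; the inverse is a bottom-up pass, and
`|det J| = ∏_{i=1}^{n−1} u_i` (internal nodes only), verified in the
tests against finite-difference Jacobians.  Sequential (caterpillar)
trees reproduce the mlr transform after a logit; the package also ships
alr and balanced-tree ilr as baseline bijections.

`HierarchicalBeta`: drawing `y_i ~ Beta(A_left(i), A_right(i))`, where
`A_c` sums a Dirichlet intensity vector over the leaves under child `c`,
gives exactly `Dirichlet(α)` for *any* topology.  Tests verify moment
closed forms, marginal KS agreement, and topology invariance.

### Tree choice

- `jaccard` (default): greedy agglomeration of per-transcript
  compatible-read sets by maximal Jaccard index, so transcripts sharing
  reads meet low in the tree.  Ties break to the lexicographically
  smallest (min transcript index, max transcript index) pair;
  zero-similarity clusters merge only after all positive-similarity
  merges, in index order (left-deep).  Candidate pairs are restricted to
  clusters sharing ≥1 read via an inverted index — exact, since
  cross-group Jaccard is zero.  The result is deterministic.
- `sequential`: the mlr-equivalent caterpillar over index order (no
  permutation optimization).
- `random`: a uniform topology (Rémy's algorithm) with uniformly
  permuted leaves, seed-reproducible.

## Base distributions and the variational fit

The approximating family is mean-field on the breaks: independent
coordinates on (0,1), pushed through the tree.  Three reparameterized
families are supported (defaults in parentheses):

- `logit_normal`: `y = logistic(μ + σ z)`, `z ~ N(0,1)`;
- `logit_skew_normal` (default): `y = logistic(μ + σ sinh(α + arcsinh z))`,
  the one-parameter sinh-arcsinh skewing;
- `kumaraswamy`: `y = (1 − (1−u)^{1/b})^{1/a}`, `u ~ U(0,1)`, density
  `a b y^{a−1} (1−y^a)^{b−1}`.

The objective is the Monte-Carlo ELBO
`E_z[log P(r|x) + log|det J| − log q_y(y)]`; maximizing it minimizes
`KL(q ‖ normalized likelihood)` without ever computing the normalizer.
Gradients are analytic: `d log P/dx` is a sparse matrix-vector product
(per-read work proportional to row support), the tree is backpropagated
in O(n) (internal node `i` receives `y_i g_L + (1−y_i) g_R + 1/u_i`, and
`dF/dy_i = u_i (g_L − g_R)`), and each family contributes exact
path/direct derivative terms (checked against finite differences to
~1e-6 relative in the tests).

Optimizer: Adam, learning rate 0.05 with cosine decay to zero over 5000
steps, 4 Monte-Carlo draws per step, and Polyak averaging of the final
25% of iterates; all config-overridable.  The schedule was chosen from
convergence diagnostics: with a constant rate and one draw per step the
smoothed ELBO is still rising at several hundred steps and marginal
means stall a few percent of a posterior sd away from the target, which
the signed-rank protocol is powerful enough to detect at 1000 draws.
Initialization starts near the likelihood mode: `μ = logit(y)` at the
breaks of the (slightly smoothed) EM estimate, `σ = 0.1`, `α = 0`;
Kumaraswamy matches its median to the same breaks at `b = 2`.  Numerical
guards: all simplex points and logistic outputs are clamped to
`[1e-12, 1−1e-12]` (the model lives on the *open* simplex; exact zeros
never occur), and densities are computed in log space.  Transcripts with
no compatible reads are never filtered; the uniform prior's `+1`
pseudo-count keeps them regularized.  Divergence (non-finite objective
or gradient) raises with the offending step number.

The fitted object (tree arrays + per-break parameters + metadata) is
stored as HDF5 — O(n) float64 values per sample — and supports O(n)
sampling and exact O(n) log-density evaluation.

## Downstream inference

- **Minimum log2 fold change**: the largest `δ` with posterior
  `P(|log2 x_a/x_b| > δ) ≥ 0.9`, computed as the 10th percentile of
  absolute paired log2 ratios; draws are paired by index (the two
  posteriors are independent, so any deterministic pairing is valid).
- **Bayesian regression** for differential expression.  The full joint
  model (approximate likelihood × prior over per-sample latent x) is
  deliberately simplified: each sample's latent log2 expression is
  summarized by the marginal mean and variance of draws from its fitted
  approximation, and per transcript
  `y_s ~ N((Dβ)_s, τ² + v_s)` with `β ~ N(0, 5²)` and `τ ~ HalfNormal(1)`
  marginalized on a grid, giving exact Gaussian-mixture posteriors for
  the effects and their tail probabilities `P(|β| > 0.5 bits)`.
  Integrating the latent x via its approximate marginal moments (rather
  than joint VI over all samples) keeps the estimator deterministic
  given the draws and is the main modeling simplification of the
  package; it still propagates quantification uncertainty, which is the
  point.  Per-sample draw substreams are derived from the fitted
  parameters, so results are invariant to sample reordering.
- **Coexpression**: each posterior draw is converted to TPM
  (`x_j/ℓ_j`, rescaled to 1e6) with a 0.1 TPM pseudocount; a Spearman
  matrix across samples is computed per draw index and averaged over 20
  draws.  Ties get average ranks; a zero-variance transcript is assigned
  correlation 0 by convention (1 on the diagonal).  Passing EM point
  estimates with `draws=1` reproduces the point-estimate analysis.

## Synthetic data

The generator emits what the method actually consumes: equivalence
classes (distinct compatibility rows with multiplicities) over genes
that partition transcripts.  Per multi-isoform gene, each transcript owns
a couple of fixed "templates" whose support is a random subset of the
gene's isoforms with conditional probabilities in [0.2, 1]; template
emission is normalized per transcript so that rows are exactly the
conditional read-class probabilities of the generative model, and the
ambiguity parameter is exactly the expected fraction of multi-transcript
rows.  Defaults: 2–4 isoforms per gene, base expression log-normal with
log-sd 2.0 (real read counts span several orders of magnitude — a
narrower prior makes every transcript comfortably detectable and the
instances unrealistically easy), effective lengths log-normal around
1.5 kb.  An optional paralog-block mode shares reads across gene pairs
to stress the tree heuristics.

Two experiment-level generators build on this: a two-condition design
(±`effect_bits` log2 shifts on a fraction of transcripts, independent
per-sample log-normal biological noise, default sd 0.2 bits) and a
coexpression cohort in which designated cross-gene pairs share a latent
per-sample factor with weight `sqrt(ρ)` (default ρ = 0.9).  Differential
effects are assigned among transcripts with expected count ≥ 10 at the
requested depth, as in standard DE benchmarks — a fold change on a
transcript that produces no reads is unobservable by construction.

What the generator does *not* emulate: sequence content and positional /
GC bias, fragment-length effects, multi-gene ambiguity beyond the
paralog-block toy, library-size variation, and annotation errors.
Passing tests therefore demonstrate correctness of the inference
machinery under the stated mixture model, not robustness to upstream
misspecification of `p_j(·)`.

## Test design and problem sizes

The reference protocols run at desk scale: goodness of fit uses ~200
transcripts and 50k reads with the full 8-chain Gibbs protocol; the
regression benchmark uses 3 vs 3 samples at 50k reads; the coexpression
cohort 12 samples at 2k reads (a deliberately shallow, single-cell-like
regime where uncertainty propagation matters most).  Statistical
assertions with many simultaneous comparisons (e.g. 3-SE moment checks
across ~180 components) allow the null-expected number of chance
exceedances rather than demanding every comparison pass, preserving
power against systematic deviations while keeping the suite
deterministic under its fixed seeds.  Median goodness-of-fit p-values
between tree heuristics are compared up to the sampling error of a
median of ~200 p-values (~0.05 SE): at this scale all three topologies
fit well and finer ranking differences are a transcriptome-scale
phenomenon.

## Known limitations

- Mean-field in break space cannot represent multimodal normalized
  likelihoods (rare, but possible with symmetric paralogs).
- KL(q‖p) is mode-seeking; residual variance underestimation shows up as
  slightly conservative minimum-fold-change bounds for heavily
  ambiguous, lightly sequenced transcripts.
- The regression model treats per-sample marginal moments as sufficient;
  strong cross-transcript posterior correlation within a sample is
  ignored at that stage (it is retained in min-lfc and coexpression,
  which consume joint draws).
- The Kumaraswamy base is noticeably less accurate than the two normal
  families (consistent with its limited shape flexibility) and is
  provided as a baseline.
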