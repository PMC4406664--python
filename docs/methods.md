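# Methods

## Phylogenetic signal

The λ model treats a trait over *n* species as multivariate normal with mean
μ**1** and covariance σ² C(λ), where C is the shared-branch-length matrix of
the (rooted, possibly multifurcating) tree and C(λ) multiplies the
off-diagonal by λ ∈ [0, 1]. λ is interpreted as the proportion of variance
attributable to Brownian-motion drift, so the search space is restricted to
[0, 1] rather than the algebraic upper bound at which C(λ) stays positive
definite. Estimation details:

- ML, not REML: σ̂² is the quadratic form divided by *n*, μ̂ the GLS mean.
- Profile likelihood over λ: 201-point grid on [0, 1], then golden-section
  refinement to 1e-6 around the best grid point. The reported optimum always
  dominates both boundary likelihoods.
- Likelihood-ratio tests against λ = 0 ("no phylogenetic effect") and λ = 1
  ("pure drift") both use χ² with 1 df. Both nulls are boundary points of the
  parameter space, so these p-values are approximate and conservative — under
  true Brownian motion the λ = 1 test rejects at nominal 5% in well under 7%
  of simulations, which is the contract the acceptance suite asserts.
- Numerical safety: before factorization the covariance diagonal receives a
  relative ridge of 1e-10 × mean(diag); log-determinants come from the
  Cholesky factor. Traits are log₂-transformed before fitting in the pipeline
  (raw-scale fitting is available).
- A zero-variance fit (constant data under the model) is degenerate; its
  log-likelihood is reported as +inf and constant traits are rejected before
  fitting. Star trees make λ unidentifiable and raise.

The implementation was cross-checked against an independent one
(R `phytools::phylosig`, ML λ): per-replicate estimates agree to ~1e-5, and a
dual-route test keeps that comparison in the suite. One caveat the comparison
made explicit: at intermediate λ (≈ 0.5) and n = 33, the ML estimator piles
up at 0 on weakly informative topologies, so the *mean* estimate across
replicates can sit 0.1–0.15 below truth on some trees. This is a property of
the estimator (both implementations agree), not of this implementation.

## Expression normalization and QC

FPKM matrices are per organ, genes × samples, with a sample sheet mapping
samples to species/organ/replicate.

- **Abundance filter.** A gene is kept only when its species-mean FPKM is
  ≥ 3.0 (boundary inclusive) in *every* species of the organ. Requiring
  complete cases keeps every downstream regression over the full species set.
- **Cyclic upper-quartile log-ratios.** For every ordered sample pair (s, r):
  genes positive in both define the pair; s is scaled by
  Q75(r)/Q75(s) (linear-interpolation percentiles over the pair's genes);
  per-gene log₂ ratios are centered on 0 by subtracting the pair's median
  (median rather than mean for robustness to asymmetric regulation;
  mean-centering sits behind a flag). Per-sample summaries are means over all
  references, per-species summaries means over the species' samples. Because
  every sample is cycled against every other, the summaries are reference-free
  — samples that are global rescalings of one vector produce exactly zero
  per-gene means, which the acceptance suite asserts at 1e-9.
- **Species-relative expression.** Per gene, log₂(species mean / minimum
  species mean); the minimum species maps to 0. Replicate-level values (log₂
  replicate / minimum species mean) are retained for the Kruskal–Wallis
  post-hoc test, which is rank-based and therefore insensitive to the shared
  per-gene reference.
- **QC.** Per-gene per-species CV = sample sd (ddof = 1) / mean across
  replicates; species with one replicate are reported missing. Species-level
  log₂ mean distributions are compared pairwise by the two-sample K-S test
  and two-tailed Welch's t-test; a species is flagged when its median CV
  exceeds 0.6 or a distribution test rejects at the configured α. Under the
  generator's default replicate noise (lognormal, CV 0.05) the median CV
  lands in [0.03, 0.07].

## Trait association

Traits enter as log₂ ratios to the minimum observed value. Regression is
deliberately nonphylogenetic OLS (see "what the tests do and do not show"
below). Per gene:

- species-level response = mean over replicates (unweighted by replicate
  count — the simplest reading of an average response);
- overall F-test without a covariate, partial F for the trait beyond the
  covariate with one;
- BH-FDR per organ × trait family (a global family is available);
- Kruskal–Wallis with tie correction on replicate-level values grouped by
  species, as a post-hoc guard that interspecies variation exceeds
  within-species variation;
- optional permutation p with the add-one estimator
  (1 + #{F* ≥ F}) / (1 + n_reps), shuffling species-level trait values so the
  replicate structure stays intact. Defaults to off; tests use 10⁴–10⁵ and
  the count is configurable to 10⁶.
- "Associated" requires both q < α and KW p < α (α = 0.05).

The residual (interaction) scan compares Y ~ 1 + t + w + t·w against
Y ~ 1 + w by partial F with BH across genes. This is one concrete reading of
"statistical interaction with body weight in the OLS model"; the model choice
is recorded in the pipeline manifest. Genes whose expression is a pure
function of body weight carry no signal in the extra terms (specificity
≥ 0.95 on the planted design).

Per-gene scans are vectorized closed-form linear algebra (annihilator
matrices for the fixed design, rank-based H via a single ranking pass);
statsmodels and scipy serve as per-gene oracles in the tests, not as the
scan implementation, for throughput reasons.

## Enrichment and clustering

Up- and down-regulated hits are tested separately per term by the
right-sided hypergeometric tail, with the organ's *tested* genes (post
filter) as the urn — enrichment against the whole genome would conflate
expression breadth with function. BH-FDR is applied jointly across
term × direction, matching two-color cluster maps built from signed
−log₁₀(q). Ward/Euclidean clustering of the term × trait score matrix is a
hand-implemented Lance–Williams recurrence with a deterministic tie-break
(merge the lexicographically smallest minimal-distance pair), verified
against scipy's linkage heights; a constant-height cut yields flat clusters.

## Conservation

Alignment columns (20 amino acids + gap; unknown residues mapped to gap)
yield Shannon entropy in bits over non-gap frequencies and a similarity
score: the mean pairwise residue similarity over unordered non-gap pairs.
The default residue-pair table is identity (score = fraction of identical
pairs); a substitution-matrix table can be loaded and min-max normalized to
[0, 1] with unit self-similarity — the choice of table is emitted in output
metadata since "similarity" admits both readings. Columns with > 50% gaps
are excluded from per-protein means; a single non-gap residue scores 1 by
convention. Group contrasts use two-tailed Welch's t-tests on per-protein
means.

## The synthetic-data generator

The generator emulates the structure of a 33-species, 3-organ mammalian
RNA-seq study and is the package's test bed; all defaults below are the
study conditions the tests and acceptance script run under.

- **Tree**: pure-birth, 33 tips, depth normalized to 1. The birth–death
  simulator stops at the n-th speciation, which leaves two zero-length tips;
  terminal branches are extended by the waiting time to the next (unrealized)
  speciation so the tree stays ultrametric with positive tip branches.
- **Traits**: seven life-history variables (gestation, weaning, maturation,
  maximum lifespan, growth rate, adult weight, metabolic rate) with
  moderate planted λ (0.39 for weight — the most constrained — up to 0.72
  for maturation) and cross-trait correlation from a shared latent loading
  (ρ = 0.8, giving pairwise log-scale correlations near 0.64). Each trait's
  deviate is √λ · (correlated BM) + √(1−λ) · (correlated white noise), so its
  marginal covariance is exactly the Pagel-transformed matrix; raw scales
  are base · 2^(scale · z) with bases/spreads giving realistic ranges
  (~100-fold lifespan, ~10⁴-fold weight at 33 species).
- **Expression**: three planted gene classes per organ — trait-linked
  (species mean = a + b·x with b scaled to a standardized effect of
  r² = 0.5 against the combined phylogenetic + iid noise; 10% of genes),
  drift (Brownian motion on the tree, rate 1.0; 60%), stable (constant + iid
  residual, sd 0.4; 30%). Baseline abundance is log-normal around
  log₂ FPKM = 5; 5% of genes are planted below the 3.0 filter so filter
  logic is always exercised. Species are duplicated or triplicated
  (P(triplicate) = 0.4) with multiplicative lognormal replicate noise of
  CV 0.05.
- **Alignments**: star-tree per-column substitution at a labeled rate
  (ancestral residue kept with probability e^(−rate), else uniform residue),
  so entropy rises monotonically with rate and saturates at log₂ 20.

Everything planted (class, linked trait, slope, λ per trait, rates) is
emitted as ground truth; identical config + seed reproduces outputs
byte-for-byte.

### What passing tests do and do not show

The generator's trait-linked genes satisfy the OLS error model at the
species level, so sensitivity/FDP statements against ground truth are
exact-model statements. Real cross-species data differ in ways the
generator deliberately mirrors only partly: drift-class genes evolve on the
same tree as the traits, and for them the nonphylogenetic F-test is
*confounded* — a drift gene can track a λ-structured trait with r² ≈ 0.5
purely through shared ancestry. Measured at 5000 genes, a drift-background
"null" organ yields at least one BH discovery in nearly every run. For this
reason the calibration checks (null FDR, planted power/FDP) use
stable-class backgrounds, where the test's null model actually holds; the
drift background is kept as a separate invariant check on the *fraction* of
q < 0.05 genes, which stays small. This is the synthetic counterpart of the
methodological caveat inherent in regressing expression on correlated
life-history gradients without phylogenetic correction — the package
implements the nonphylogenetic design faithfully and quantifies, rather
than hides, its confounding behavior.

At the global null, mean false-discovery proportion equals the BH FDR
exactly (α, all-null case), so the 100-run empirical mean is asserted
against α plus twice its binomial standard error; the acceptance script
reports the raw measured mean.

## Pipeline and problem sizes

`run_pipeline` chains simulate → QC → normalize → λ fits → associate →
residual scan → enrich → conserve from one YAML-loadable config; every
stochastic stage draws a seed derived from the run seed and the manifest
records versions, seeds and analysis decisions, making reruns
bit-identical. The default study — 3 organs × 5000 genes × 33 species with
2–3 replicates — completes in well under a minute on one CPU; the
acceptance script's full battery (600 λ fits, 1000 LRT simulations, 100
null organs, 3 power organs, 2 × 10⁶ permutations, exact enumerations and a
full pipeline pass) runs in a few minutes.

## Known limitations

- No phylogenetic regression (PGLS) and no OU or multivariate trait models:
  the analysis is deliberately nonphylogenetic at the gene level, with λ
  reserved for trait-level signal; the confounding consequence is
  characterized above.
- λ p-values at the boundaries are approximate (χ² df = 1); no mixture
  correction is applied.
- The permutation test is implemented for the covariate-free model only.
- The generator's alignments are i.i.d. per-column star-tree substitutions —
  adequate for entropy/similarity contrasts, not for tree-aware sequence
  evolution.
- GO-style annotation content, ortholog inference and read-level processing
  are upstream of the package and out of scope.
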