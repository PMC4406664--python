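# phyloexpr

Comparative analysis of mammalian life-history traits and bulk organ
transcriptomes. The package asks how much of the variation in traits such as
maximum lifespan, maturation time and body weight across a mammalian phylogeny
is explained by shared ancestry, and which genes' cross-species expression
profiles track the gradients of those traits (and their allometric residuals)
in liver, kidney and brain. It is aimed at researchers in molecular evolution
and comparative transcriptomics who want the full analysis chain — from a
Newick chronogram and per-organ FPKM matrices to enrichment maps and
conservation contrasts — as tested, scriptable Python, exercised end-to-end on
synthetic studies with known ground truth.

## The models at the core

**Phylogenetic signal (Pagel's λ).** For a trait vector *y* over *n* species
with tree covariance **C** (C<sub>ij</sub> = shared root-to-MRCA branch
length), the λ model is

> y ~ N(μ**1**, σ² C(λ)),  C(λ) = λ C + (1 − λ) diag(C),  λ ∈ [0, 1]

λ = 1 is pure Brownian-motion drift, λ = 0 phylogenetic independence; λ is the
proportion of trait variance attributable to the tree. `fit_lambda` maximizes
the profile likelihood (201-point grid + golden-section refinement, ML
variance estimator) and reports likelihood-ratio tests against both
boundaries (χ² df = 1; approximate, since the nulls sit on the boundary).

**Trait association.** Per gene *i*, the species-level mean relative
expression Y<sub>i</sub> is regressed by ordinary least squares on the
log₂-relative trait x₁ (optionally with a covariate x₂):

> Y_i = β₀ + β₁ x₁ + β₂ x₂ + ε,  ε ~ N(0, σ² I_n)

with an F-test, Benjamini–Hochberg FDR across the organ × trait family, a
Kruskal–Wallis post-hoc test on replicate-level values grouped by species
(interspecies variation must exceed within-species variation), and an
optional permutation null that shuffles species-level trait values. The
allometric (residual) scan compares Y ~ 1 + t + w + t·w against Y ~ 1 + w by
partial F to find genes tracking a trait beyond body weight. Expression
enters as log₂ ratios after a 3.0-FPKM abundance filter and upper-quartile /
cyclic pairwise log-ratio normalization. Enrichment of up/down gene sets is
right-sided hypergeometric with the tested genes as the urn; conservation of
up- vs down-regulated ortholog groups is compared via per-column identity
similarity and Shannon entropy (bits) with Welch's t-tests.

## Worked example

Simulate a 33-species study and estimate the phylogenetic signal of maximum
lifespan:

```bash
phyloexpr simulate --out demo --seed 7 --n-genes 1000
phyloexpr fit-lambda --tree demo/tree.nwk --traits demo/traits.tsv \
    --trait max_lifespan_years --log2
```

```
lambda_hat=0.6430 sigma2=4.719 logL=-66.917 p_vs_random=0.01838 p_vs_bm=0.5477
```

The generator planted λ = 0.65 for lifespan; the fit recovers 0.643. The LRT
against λ = 0 rejects (P = 0.018): lifespan carries real phylogenetic signal.
The LRT against λ = 1 does not reject here — a single 33-species realization
has limited power to separate moderate λ from pure drift.

Scan liver expression for genes tracking maturation time:

```bash
phyloexpr associate --matrix demo/liver.tsv --samples demo/samples.tsv \
    --traits demo/traits.tsv --trait maturity_days --out demo/assoc.tsv
```

```
155 associated genes -> demo/assoc.tsv
```

Each row of `assoc.tsv` carries the gene, slope direction, r², F p-value, BH
q-value and Kruskal–Wallis p; a gene is "associated" when q < 0.05 and
KW p < 0.05. The 155 hits against `demo/truth.tsv` are dominated by the
planted trait-linked class. `phyloexpr run` chains all stages (QC →
normalization → λ fits → association → residual scan → enrichment →
conservation) and writes a manifest with every seed, so any run is
bit-reproducible.

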