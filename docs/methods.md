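# Methods

`lncnet` implements the integrated lncRNA/mRNA tumor-vs-normal analysis
workflow used with two-channel expression microarrays on small paired
cohorts: moderated differential expression under a random-variance model,
hierarchical clustering of the differential signature, gene-set
over-representation, interaction-network centrality ranking, competing-
endogenous-RNA (ceRNA) triplet discovery, and per-group co-expression
networks ranked by degree differences.  This note records the models, their
assumptions, the tunable parameters, and the numerical and design choices
made where the design was genuinely open.

## Random-variance-model moderated t-test

Small cohorts make per-gene variance estimates unstable.  The random
variance model assumes gene-wise precisions share a gamma prior,

    1/sigma_g^2 ~ Gamma(shape a, scale b),

equivalently the variances are inverse-gamma.  If `s_g^2` is the pooled
two-sample variance of gene *g* on `m = n1 + n2 - 2` degrees of freedom,
this prior implies the marginal

    a * b * s_g^2  ~  F(m, 2a),

which is what `fit_rvm_hyperparameters` maximizes the likelihood of across
all genes (L-BFGS-B on `(log a, log b)` from a fixed 12-point multi-start
grid; deterministic).  The moderated statistic replaces `s_g^2` by the
posterior-shrunken variance

    s~_g^2 = (m * s_g^2 + 2/b) / (m + 2a),

a weighted mean of the data variance and the prior fixed point `1/(a*b)`
(shrinkage moves toward the prior, never past it), and refers

    t_g = (mean_tumor - mean_normal) / sqrt(s~_g^2 * (1/n1 + 1/n2))

to a t distribution with `m + 2a` degrees of freedom.  As `a -> 0` and
`1/b -> 0` this reduces exactly to the classical pooled-variance t with
`df = m`; the suite asserts the reduction numerically at `a = 1e-8`,
`1/b = 1e-8` and verifies type-I calibration (fraction of null p < 0.05
within Monte-Carlo error of 0.05) under the model's own generator.

The test is the unpaired two-sample formulation.  Pairing labels, when
present, are carried through the containers and used by the ddCt module;
a paired moderated test is out of scope.

**Parameterization.**  Conventions for gamma/inverse-gamma scale parameters
differ across the literature; everything here is fixed to the single
convention above (`precision ~ Gamma(shape=a, scale=b)`, hence
`a*b*s^2 ~ F(m, 2a)`), and the synthetic generator draws from exactly this
family so hyperparameter recovery is a closed-loop test.

## Differential-expression filter and fold change

Fold change is the antilog of the difference of group means on the log2
scale, `fc = 2^(mean log2 tumor - mean log2 normal)` (printed fold changes
could also be ratios of linear-scale means; the antilog convention is fixed
here).  A probe is called up-regulated when `fc >= 2` and `p < 0.05`
(inclusive on the fold-change threshold, strict on p, matching the printed
filter), down-regulated when `fc <= 1/2` and `p < 0.05`.  FDR is
Benjamini–Hochberg across all tested probes and is reported alongside; the
filter itself uses the raw p-value, as published.  Lists are ordered by p,
then |log2 fc|, then probe id, so results are invariant to input order.

## ddCt (2^-ddCt) relative quantification

For qPCR validation tables: per sample `dCt = Ct_target - Ct_reference`
(reference gene required in every sample), `ddCt = mean dCt(case) - mean
dCt(control)`, relative expression `2^-ddCt`, with a two-sided two-sample
t-test on per-sample dCt values.

## Hierarchical clustering

Agglomerative binary clustering with four linkage rules — single, complete,
average, centroid (the classic quartet; which four the original analyses
used is not stated anywhere, so the common set is fixed here).  The default
metric is correlation distance `1 - Pearson r`, standard for expression
profiles; Euclidean is available by flag.  Merge order and tie-breaking
follow scipy's deterministic implementation.  Group separation is scored by
cutting the tree into two clusters and reporting label purity (1.0 =
perfect tumor/normal split, 0.5 = chance for balanced groups).  On the
default synthetic cohort the planted 2-fold signature separates the 18
samples perfectly.

## Over-representation analysis

Each gene set is tested with a two-sided Fisher exact test using the
point-probability rule: the p-value sums hypergeometric probabilities of
all tables whose probability does not exceed the observed one (ties counted
with a 1e-7 relative slack, the convention of common exact-test
implementations).  A chi-square test without Yates correction (flag to
enable) is reported alongside.  The universe is every annotated lncRNA/mRNA
gene on the array — the standard microarray ORA choice — and set membership
is intersected with the universe before testing; terms with no DE member
are omitted.  FDR is Benjamini–Hochberg over the tested terms, and
`-log10(p)` is included for bar-chart reporting of top terms.

## Interaction-network centrality

The functional-interaction graph arrives as a SIF-style typed edge list
(ten interaction codes: a, b, c, p, u, m, inh, ex, dep, ind).  Edge types
and directions are metadata only — all statistics treat the network as
untyped and undirected, since the published core-gene tables are type-blind.
The subnetwork induced on the DE genes (isolated DE genes retained at
degree 0) is scored by degree (number of distinct neighbors) and shortest-
path betweenness, normalized by `2/((N-1)(N-2))` so scores lie in [0, 1];
raw pair counts are available by flag because published small values (e.g.
0.0098 at degree 32) are consistent with normalized scores on a large
network but the convention is never stated.  Core genes keep betweenness
`>= 0.005` (inclusive, as printed) ranked by betweenness, then degree, then
id.  Betweenness comes from networkx's Brandes implementation and is
checked in the suite against two independent brute-force oracles (explicit
simple-path enumeration on every isomorphism class of graphs up to 7 nodes;
BFS path-count identity on random graphs up to 40 nodes).  Unreachable
pairs contribute nothing.

## ceRNA triplets

A (miRNA, lncRNA, mRNA) trio is a competing triplet when (i) both
transcripts appear as targets of the miRNA in the input target map, (ii)
their Pearson correlation reaches the positive threshold, and (iii) each
transcript correlates with the miRNA at or below the negative threshold.
Target relations are an input file: sequence-based site prediction and
binding-energy computation are explicitly out of scope.  The correlation
thresholds default to (+0.8, -0.8); no published cutoff exists, so they are
required, logged configuration.  miRNA expression is optional (integrated
lncRNA+mRNA platforms do not measure it): `strict` mode requires it,
`lenient` mode applies only the transcript-transcript constraint and flags
rows as target-only.  Output order is lexicographic and the triplet network
summary reports per-molecule participation counts with all tied hubs listed.

## Per-group co-expression networks

Within each group separately, every mRNA–lncRNA, mRNA–mRNA and
lncRNA–lncRNA pair is correlated over that group's samples, and pairs with
`|r| >= 0.92` become edges (the cutoff is read as a magnitude threshold
because published pair tables contain negative coefficients under the same
cutoff; the sign is kept as an edge attribute).  Core genes are ranked by
the absolute difference of their degrees between the tumor and normal
networks — the differential-co-expression signature — with ties broken by
tumor degree, then id.  Note that at n = 9 samples per group the null
distribution of r is wide: |r| >= 0.92 has probability ~4e-4, so a
1000-gene network contains a few hundred noise edges per group.  This is
intrinsic to the design size, and it is why core-gene selection uses degree
*differences* rather than raw degrees.

## Synthetic-data generator

The generator emulates the target study design and is itself first-class,
tested code.  Defaults (all overridable): 9 tumor/normal pairs; 700 mRNA +
300 lncRNA + 40 miRNA features; gene variances from the inverse-gamma family
at (a=2.0, b=1.5); baselines N(8, 1.5^2) log2 units; 10% planted up and 5%
planted down genes (100 up / 50 down) shifted by log2_effect = 2.0 in tumor;
10 planted lncRNA–mRNA pairs at |r| = 0.97; 3 planted ceRNA triplets
(miRNA–transcript r = -0.90, transcript–transcript r = 0.95); decoy:planted
ratios 10:1 for target relations and 5:1 for gene sets.  Identical seeds
give identical bundles.

All planted correlation uses variance-preserving latent-factor loadings
(`sqrt(rho)*factor + sqrt(1-rho)*noise`), so the marginal variance
distribution — and hence the closed-loop hyperparameter-recovery test —
is untouched by planted structure.  Three deliberate design choices:

* **Planted pairs form one tumor-only module.**  All planted pairs share a
  single latent factor active in tumor samples only.  This models
  disease-specific co-expression rewiring and gives module members large
  tumor-vs-normal degree differences.  Isolated degree-1 pairs could not be
  distinguished from the noise-edge background at n = 9 (see above), so a
  module is the structure a degree-difference ranking can genuinely detect.
* **Triplets use two factors.**  A miRNA factor entering the miRNA profile
  positively and both transcripts negatively sets the sponge signature; a
  second transcript-only factor lifts the transcript pair correlation above
  the miRNA-transcript magnitude (0.95 vs 0.90), keeping planted triplets
  clearly beyond the (0.8, -0.8) calling thresholds at n = 18 samples.
* **Decoy gene sets are base-rate matched.**  Each decoy set contains
  planted DE genes at exactly the background DE fraction, making decoys
  unenriched by construction.  Uniformly drawn decoys would have uniform
  Fisher p-values — occasionally "significant" by design — which is the
  wrong null for a ground-truth fixture.

The interaction graph links planted DE genes into a connected depth-2 core:
a hub wired to 30 spokes, remaining planted genes attached round-robin to
spokes, plus ~2x-gene-count background edges that never join two planted DE
genes (so the planted core, not the background, carries the centrality
signal).  Gene sets include one truly up-enriched and one truly
down-enriched set plus the matched decoys.  Decoy target relations avoid
genes of the planted co-expression module so that the fixture's false-triplet
count is structurally zero under the sign constraints.

What the generator does **not** emulate: probe-level artifacts, dye and
spatial effects, non-Gaussian noise, correlated null genes (beyond the
planted structures), annotation errors, or multiple probes per gene.
Passing the suite therefore demonstrates correctness of the statistical
machinery and recoverability of planted structure under the model's own
assumptions — not robustness to real-array artifacts.

## Numerical choices and degenerate inputs

* Fisher two-sided p via scipy's hypergeometric pmf over the full support;
  exact-integer enumeration agrees to < 1e-10 on every table with N <= 60.
* Optimizer for (a, b): bounded L-BFGS-B in log space, 12 fixed starts;
  degenerate inputs (constant variances, < 100 genes, non-positive values)
  raise immediately.
* Zero-variance rows: correlation distance raises (naming the row); the
  co-expression builder and triplet caller skip such genes.
* `t = 0, p = 1` when group means are identical; moderated SE is always
  positive for `a, b > 0`.
* Writers emit UTF-8, tab-separated, 6-significant-digit reals with fixed
  column order: write -> read -> write is byte-stable.
* All ranking ties break deterministically (documented per operation), so
  outputs are reproducible across runs and platforms.

## Problem sizes used by the checks

The acceptance script and suite run at the study's own scale: the default
1000-gene, 18-sample cohort end to end; 20,000 variances for hyperparameter
recovery; 10,000 null genes for type-I calibration; 5,000 genes for the
variance-marginal KS check; all ~1,250 isomorphism classes of graphs up to
7 nodes plus 100 random graphs up to 40 nodes for betweenness; all 2x2
tables with N <= 60 for the Fisher oracle.

## Known limitations

* Unpaired test only; the 9-pair design's pairing is used for display and
  ddCt, not inference.
* Gene-level collapse keeps the highest-mean probe; no probe averaging.
* No GO-graph propagation, GSEA, WGCNA-style soft thresholding, or partial
  correlations.
* ceRNA calling depends entirely on the supplied target map; no sequence
  or binding-energy evidence is computed.
* Published per-gene values from the original cohort (specific centralities,
  correlations, fold changes) depend on external databases and raw data and
  are not reproduction targets; the pipeline reproduces the method, and the
  synthetic fixture provides the ground truth the method is verified
  against.
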