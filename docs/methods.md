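# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical choices that matter. Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Urodynamic indices

`BCI = PdetQmax + 5·Qmax` and `BOOI = PdetQmax − 2·Qmax` are exact
arithmetic on the inputs (cmH2O, ml/s). The HP/MP split is inclusive at
PdetQmax ≥ 90 cmH2O. Obstruction classes follow the standard BOOI
nomogram bands — below 20 unobstructed, 20–40 equivocal, above 40
obstructed; the band edges are module constants and function arguments,
since only the "<20 means relief" bound is clinically forced and the
other two are convention.

## RNA-seq differential expression

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over genes nonzero in all samples; the median is taken on the
ratio scale, which matters for even sample counts). Genes with zero
counts across both contrast groups are dropped before testing and before
BH — they are not part of the multiple-testing universe. Log2 fold
changes use a +0.5 pseudo-count on normalized group means so they stay
finite at zero.

Two tests with distinct mechanics implement the dual-tool decision
contract:

**Conditional exact-style test (`nb_exact`).** A common dispersion α is
estimated by the pooled moment identity Σ(var − μ) = α·Σμ² over genes,
using within-group variances (pooled ratios avoid the small-*n* downward
bias of per-gene ratio medians). Normalized counts are rounded to
integers; conditional on a gene's total, the group-A sum follows the
conditional law of independent NB sums with sizes n_A/α and n_B/α. The
two-sided *mid-p* sums outcomes strictly less likely than the observed
split plus half the boundary mass; plain summation leaves a visibly
conservative null CDF at typical totals. Enumeration is exact up to 10⁴
outcomes; beyond that a normal approximation to the conditional law takes
over (mean and variance from the conditional moments).

**Moderated Wald test (`nb_wald`).** Per-gene pooled within-group
variances s²_g (d_g = n_A + n_B − 2 df) are shrunk toward a quadratic
log-variance vs log-mean trend by empirical Bayes: the prior df d₀ and
scale are moment-matched on log variance ratios exactly as in the
proteomics moderated *t* below. The statistic is the delta-method Wald
ratio lfc / SE with SE² = s̃²_g (1/(n_A m_A²) + 1/(n_B m_B²)) / ln²2,
referred to a *t* with d₀ + d_g df. A fixed-weight dispersion shrink
cannot absorb true dispersion heterogeneity across genes and leaves the
null p-value distribution visibly non-uniform; under the hierarchical
variance model the estimated-prior form is calibrated by construction,
which the null-calibration tests verify empirically.

A *consensus DEG* is significant in both tests at BH-adjusted p < 0.1
(the study-wide rule) with the same fold-change sign; discordant signs
are excluded. Bookkeeping over before/after consensus sets is pure set
arithmetic, so |before| = |normalized| + |persistent| and |after| =
|persistent| + |de-novo| hold identically.

One caveat the tests encode: p-values within a single dataset share the
estimated size factors, variance trend and prior, so they are weakly
correlated; null-calibration KS checks therefore pool three independently
simulated datasets rather than testing one.

## Classifier-gene selection

PCA operates on log2(normalized count + 1) with samples as observations,
centered and not scaled (scaling is exposed as an argument). Loadings are
right singular vectors with a deterministic sign convention (largest
|loading| positive). "Top or bottom 20% of the loading range" is read
literally as the min–max span per PC: feature selected iff loading ≥ hi −
0.2·(hi − lo) or ≤ lo + 0.2·(hi − lo), boundaries inclusive, union over
the top six PCs capped at the number that exist (five in a 3 + 3 design,
with a warning). The classifier is the intersection of that union with
the consensus DEGs; separation of sample groups on the
classifier-restricted PCA is quantified by the silhouette on the first
two score dimensions.

## Label-free proteomics

Intensities are log2; zeros and blanks in the input are missing. The
detection filter keeps proteins with ≥2 observed values in at least one
replicate group. Imputation is two-tier:

* **Tier 1** (block with ≤1 observation): missing entries are drawn from
  Normal(μ_s − 2.5σ_s, (0.3σ_s)²), where μ_s and σ_s are the observed
  mean and SD of the entry's *sample column*. The per-column reading is
  the Perseus convention; a per-protein reading is unusable because
  single-detection rows carry no spread estimate.
* **Tier 2** (block with ≥2 observations): missing entries take the
  normal-MLE mean of the block's observed replicates — deterministic, so
  cycle-to-cycle variation isolates the stochastic tier.

The moderated *t* shrinks per-protein pooled variances toward a prior
(d₀, s₀²) estimated by moment matching of log s²_g against a scaled-F /
log-chi-square model (trigamma inversion by Newton iteration); t̃ =
lfc/(s̃_g √(1/n_A + 1/n_B)) on d₀ + d_g df. d₀ → ∞ degenerates to a
pooled-variance z; d₀ = 0 to the ordinary two-sample t (both limits are
unit-tested).

The volcano significance curve requires |log2FC| > 1 **and** −log10 p_adj
≥ −log10 0.05 + c/(|log2FC| − 1). The hyperbolic form is the simplest
curve satisfying both stated constraints (hard fold-change asymptote;
0.05 reached only at asymptotically high fold changes); the curvature
c = 0.5 is a package default and an argument, since no constant is
recoverable from the procedure's description. c = 0 degenerates to the
rectangular rule. BH is applied within each imputation cycle over
filter-passing proteins. Reported statistics come from cycle 0 of 20;
*consistent* = curve-significant in every cycle.

## Ontology enrichment and semantic clustering

Annotations are true-path closed (child genes propagate to ancestors).
ORA is the one-sided hypergeometric upper tail P(X ≥ k) per term; the
retention rule is **raw** p < 0.1 — deliberately unadjusted, matching the
stated threshold semantics; callers can BH-adjust the returned column.
The universe is the set of genes detected in the count matrix (nonzero in
≥1 sample). IC(t) = −log(|genes(t)|/|genes(root)|); Resnik similarity is
the maximum IC over common ancestors (a term is its own ancestor),
normalized by the corpus maximum IC so the 0.7 pruning threshold lives on
[0, 1]. Pruning is greedy by ascending p with term-id tie-breaks, hence
order-independent. Binary cut recursively bipartitions the
average-linkage dendrogram of 1 − sim, stopping when a block's mean
off-diagonal similarity reaches 0.85 (the method's conventional
homogeneity cutoff; configurable) or the block has <3 terms; the input is
canonically ordered first so permuted matrices give identical partitions.
Display outputs are tables only (tile sizes, gene frequencies, per-term
fold-change lists); no figures are rendered.

## TF regulons

Databases merge with per-source provenance (TRED / ITFP / TRRUST /
Marbach / synthetic) so known vs predicted targets remain filterable. A
TF's trajectory category is a pure function of its per-group before/after
DE booleans with precedence persistent → normalized_after → de_novo →
unchanged; `normalized_after` requires that every group DE before is no
longer DE after. Target profiles are clustered with d = 1 − Pearson and
average linkage; constant rows (undefined correlation) go to a separate
flat bucket. The default k = 5 mirrors the number of target clusters the
motivating analysis reported, and is a parameter. The per-cluster
`down_after` flag means the cluster's mean fold change drops from before
to after in every patient group.

## Synthetic generators

All generators take a seed and return ground truth; identical
(parameters, seed) give bit-identical output.

* **Counts**: NB via gamma–Poisson with var = μ + αμ². Gene baseline
  means are log-normal around 150 (log-SD 1.0), per-gene dispersions
  log-normal around the requested mean (log-SD 0.3), and per-sample
  library factors log-normal(0, 0.2) — modest depth variation typical of
  a single-batch bulk experiment. Planted fold changes have magnitude
  exactly `lfc_scale`, signs split 50/50, so loading-based selection sees
  a homogeneous effect tier. The five-group study generator assigns each
  planted gene a trajectory (40% persistent, 40% normalized, 20% de
  novo) and a scope (60% both groups, 20% HP-only, 20% MP-only).
* **LFQ**: per-protein log2 means Normal(23, 2.0) — a typical LFQ scale
  and dynamic range — with replicate noise SD 0.3. Missingness is
  deterministic censoring below each sample's `censor_quantile` quantile
  plus a 2% completely-at-random background, so both imputation tiers are
  exercised. Planted shifts default to the magnitude given per call.
* **Ontology**: a random rooted is_a DAG (occasional second parents make
  it a genuine DAG); every gene is annotated somewhere, so the root's
  closed set is the universe. An optional focus-gene mechanism
  concentrates chosen genes in a few terms to plant enrichable signal.
* **TF tables**: exact regulon sizes with a controllable shared-target
  fraction; TF identifiers can be drawn from the measured gene universe
  so TFs themselves appear in DE results (a regulon never lists its own
  TF, which can shrink such a regulon by one).
* **Urodynamics**: PdetQmax from the group normals 107 ± 20.4 → 40.6 ±
  5.5 (HP) and 55 ± 21.7 → 22 ± 2.64 cmH2O (MP), truncated at zero by
  resampling; Qmax (7 ± 2 before, 16 ± 4 after ml/s) and residual volume
  (150 ± 60 before, 25 ± 12 after ml) are plausible configured ranges
  kept as module constants.

What the generators do **not** emulate: batch effects, gene–gene and
protein–protein correlation, compositional library effects, realistic
annotation structure (real GO is far deeper), peptide-level artifacts, or
any real gene symbols. Passing recovery tests therefore demonstrates that
the pipeline's logic is correct and calibrated under its stated model,
not that it would achieve the same operating characteristics on real
tissue data.

## Problem sizes and numerics

Test and acceptance runs use deliberately compact problem sizes — 2 000
genes for recovery and power checks, 3 × 2 000 pooled genes for NB null
calibration, 5 000 features for the moderated-t null, 400 proteins for
the 20-cycle consistency study, 10⁶ draws for the imputation-distribution
check, and an 800-gene end-to-end run — chosen so the full suite
completes in well under a minute per module while leaving the Monte-Carlo
error of every asserted quantity far below its tolerance. Dispersions are
clipped at 10⁻⁸; conditional-law enumeration caps at 10⁴ outcomes; BH
adjustment propagates NaNs and excludes them from the test count;
trigamma inversion runs Newton to 10⁻¹⁰ relative change with closed-form
guards at both extremes. Ties at loading-range boundaries are included;
pruning and representatives break ties by term id; PCA signs are fixed by
the largest-|loading| convention.

## Known limitations

The NB tests share a normalization step, so their consensus is less than
two independent opinions; the exact test assumes a common dispersion
across genes; delta-method standard errors degrade for genes with mean
normalized counts near zero (such genes are heavily pseudo-count damped
instead of removed). Down-shift imputation can manufacture large apparent
fold changes for proteins near the detection boundary that drop out of
one group by chance — the significance curve's fold-change asymptote and
the consistency flag suppress most but not all of these, which is visible
as the nonzero FDR the acceptance script reports. The ORA layer tests
every term without multiplicity adjustment by design; its output is a
screening list, not a confirmatory one.
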