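# Methods

## Model and procedure

The pipeline links per-gene expression across mammalian species to log2
maximum lifespan (MLS). Expression input is assumed batch-corrected log2 TPM
with one row per gene (joined on 1:1 orthologs upstream); missing entries
(species without data for a tissue) are carried as an explicit mask and never
imputed. Genes observed in fewer than 10 species are excluded; the survivors
define the "investigated genes" background used by every overlap and
enrichment test.

Two association tests are run per gene.

- **Spearman**: average-rank ρ between expression and log2(MLS) over the
  gene's observed species; two-sided p by full permutation enumeration when
  n ≤ 7 (the null is cached per tie pattern), otherwise the t approximation.
  Constant rows are untestable and are removed from both the tested set and
  the background.
- **PGLS**: closed-form generalized least squares of expression on
  [1, log2 MLS] with error covariance proportional to the Brownian-motion
  matrix V (shared root-to-ancestor branch length; V[i,i] = root-to-tip
  distance). This matches the default corBrownian structure of ape/nlme;
  no Pagel's λ or OU transform is estimated, so ML-vs-REML distinctions do
  not arise — the fixed-V GLS is exact. Slopes are tested two-sided against
  t with n − 2 df. Over a tree ensemble the per-tree fits are aggregated by
  the **maximum p-value**, and the reported slope is taken from the max-p
  fit, since that is the fit the significance call rests on. Slope-sign
  disagreement across trees is logged, and such genes are excluded from
  signed call sets: their direction is not interpretable.

Covariance submatrices are used directly for genes with missing species —
restricting V to the observed species is exactly equivalent to pruning the
tree first (degree-2 collapse preserves shared path lengths), which
`prune_tree` also implements and the tests cross-check.

**FDR.** The Benjamini–Krieger–Yekutieli two-stage step-up: stage 1 is BH at
q′ = q/(1+q); with r₁ ∉ {0, m} rejections the null count is m̂₀ = m − r₁ and
stage 2 re-runs BH at q′ with m̂₀. Reported q-values are BH adjustments with
m̂₀ in place of m, scaled by (1+q), so thresholding them at the q the
procedure was run with reproduces the rejection set exactly. Calls use a
strict q < level. The statsmodels `fdr_tsbky` implementation is used as an
independent cross-check in tests, never as the implementation.

**Concordance.** Given signed sets A and B restricted to a universe of N
genes, concordant/discordant counts are compared with their independence
expectations E = Σ_s |A_s||B_s|/N (resp. with B's signs flipped). The odds
ratio conditions on A — OR = [O/(n_A−O)]/[E/(n_A−E)] — because A (the MLS
call set) is the fixed query in every comparison; the discordant *count* is
symmetric in A and B but the OR is not, which the tests document.
Significance is a two-sided exact binomial test (minimum-likelihood-sum
convention) of O in n_A trials at chance rate E/n_A; the binomial null
slightly understates the without-replacement variance, making the test mildly
conservative — acceptable for sets that are small relative to the universe,
and verified by calibration (type-I rate ≈ 0.04 at α = 0.05 for 300-gene sets
in a 5000-gene universe). An alternative 2×2-table odds ratio and a
trials-on-B convention exist behind flags; observed-vs-expected with trials
on A is the default.

Auxiliary comparisons: per-gene Welch (unpaired, unequal-variance) t tests
between two panels' correlation-coefficient profiles, and a one-sample
Wilcoxon signed-rank test (exact for n ≤ 25 without ties, normal
approximation with continuity correction otherwise). The Welch choice is
deliberate — nothing ties coefficients pairwise across tissues.

**Enrichment.** Per-term 2×2 Fisher exact tests (two-sided,
minimum-likelihood-sum) of the query against an explicit background;
sample OR ad/bc reported as undefined on zero cells unless the
Haldane–Anscombe 0.5 correction is requested (display only). Libraries are
GMT files. Background sensitivity is real and tested: restricting the
background changes p-values, so the investigated-gene background is always
passed explicitly.

**Motif scanning.** PFMs are read from JASPAR text; a pseudocount (default
0.01, well below JASPAR count resolution) is added per cell before column
normalization, and log2 odds are taken against a zero-order background
(uniform by default; `estimate_background` derives a strand-symmetrized
background from the input promoters). Scores are discretized on a single
integer grid — the widest-ranging column spans `granularity` (default 1000)
levels — so column scores stay additive, and the exact null distribution of
a background window's score is built by convolution across columns. A
window's p-value is the null tail probability at its integer score; for
width ≤ 6 this equals brute-force enumeration over all 4^w windows, which the
tests assert. Both strands are scanned (the reverse strand uses the
reverse-complemented integer matrix; strand-symmetric backgrounds make the
null identical), overlapping hits are all kept, windows containing N are
skipped, and the default report threshold is p < 1e-4. Batch scanning
concatenates promoters with N separators and is verified against the
per-sequence scanner.

**Co-evolution trend.** Per species, the called gene set and the background
gene set each yield a presence ratio (fraction of promoters with ≥ 1 hit)
and a mean hit count. The presence metric becomes a true odds ratio
[p₁/(1−p₁)]/[p₀/(1−p₀)] — species at p ∈ {0,1} are dropped as undefined —
while the mean-count metric is a plain ratio of means (an odds transform of
an unbounded mean is undefined). Each (motif, metric) series over ≥ 5 usable
species is Spearman-correlated with MLS; BKY FDR (chosen for consistency with
the association stage) is applied across all tests; a motif is called only
when both metrics are significant at FDR < 0.05 with the same trend
direction.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed); byte-identical on
repeat.

- `simulate_tree`: Yule (pure-birth) trees rescaled to unit height;
  ensembles share the topology with log-normal branch-length jitter
  (σ = 0.1), a desk-scale stand-in for posterior tree samples whose members
  are highly correlated. Default ensembles use 10 trees.
- `simulate_trait_bm`: Brownian motion of rate σ² down the tree; the trait
  is log2(MLS) directly (root 5 ≙ 32 years, rate 1), exported as
  MLS = 2^trait.
- `simulate_expression`: planted genes follow sign · slope · trait plus
  Brownian noise (SD 0.1) plus i.i.d. noise (SD 0.45 ... see below); null
  genes are noise only; per-cell missingness (default 10%) with rows redrawn
  to keep ≥ 10 observed species. Defaults (slope 1, phylo SD 0.1, iid SD
  0.54) put the planted genes' expected |ρ| near 0.8 while keeping the
  phylogenetic share of null-gene variance small enough (~3%) that the rank
  test's error control stays near nominal across tree/trait realizations —
  with a larger phylogenetic share, rank-test false positives become
  realization-dependent and heavy-tailed, which is precisely the pathology
  PGLS exists to fix and what the pipeline's dual-method design addresses.
- `simulate_signed_partner_set`: weighted sampling without replacement where
  sign-matched anchor items get weight w solved from the target
  concordance-OR equation (w = 1 at target 1, i.e. uniform); calibrated by
  Monte Carlo (median estimated OR 2.87 at target 3, 0.96 at target 1).
- `simulate_promoters`: i.i.d. uniform background sequence; a gain trend
  plants a deterministic per-species insertion total, linear in MLS rank
  (0 → `max_insertions` per promoter on average), spread randomly over
  genes so per-species mean counts are exactly monotone while presence
  ratios stay off the 0/1 boundary. Insertions are the motif consensus and
  never overlap.
- `random_motif` (Dirichlet columns, concentration 2) produces
  JASPAR-like PWMs with dense null score distributions, so background hit
  rates near a scan threshold behave like real motifs; `synthetic_motif`
  builds sharp consensus motifs for unambiguous planting.

Not emulated: read-level sequencing noise, batch artifacts (inputs are
assumed corrected), block-missing tissue structure (per-cell missingness is
the default), indel/rearrangement evolution of promoters, and inter-gene
expression correlation. Passing tests therefore demonstrate the statistical
machinery under the stated generative model, not robustness to the full mess
of real compendia.

## Numerical choices and problem sizes

- Covariance Cholesky with a 1e-10 jitter tolerance in PSD checks; GLS
  singularities (constant predictor, non-PD V) raise typed errors.
- Perfect fits (zero residual) report p = 0 with an infinite t rather than
  dividing by zero; degenerate Welch inputs (zero variance, unequal means)
  report p = 0 with a logged flag.
- Exact Spearman permutation nulls are cached per (n, tie-pattern).
- Score discretization: granularity 1000 (≥ 100 enforced); refining to 2000
  moves p-values by < 1e-6 on typical motifs (tested).
- Pipeline stage seeds derive from the master seed via
  `SeedSequence([master, stage_index])`, so stages re-run in isolation
  reproduce byte-identical outputs.
- Tested problem sizes: the end-to-end recovery analysis uses 29 species ×
  2000 genes × 200 planted with a 10-tree ensemble; the trend-recovery
  analysis uses 20 species with 25 query and 300 background promoters. These
  are the package's default study conditions; all scale linearly if raised.

## Known limitations

- The max-p ensemble aggregation is conservative and has no analytic null;
  its calibration is inherited from the per-tree t tests.
- The binomial overlap test ignores the hypergeometric variance reduction;
  for query sets a large fraction of the universe it becomes noticeably
  conservative.
- The mean-count "odds ratio" is a ratio of means; with very sparse
  background hit rates its per-species denominator is noisy, so trend power
  depends on the background panel size (see the generator notes above).
- Promoter headers follow the package's own `geneID|speciesID` convention;
  other conventions need renaming upstream.
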