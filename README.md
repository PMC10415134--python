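# lifecon

Cross-species transcriptomics of lifespan: does gene expression that tracks a
species' maximum lifespan (MLS) look like the expression changes of aging?
`lifecon` implements the full analysis chain needed to ask that question —
trait–expression association across species, signed gene-set concordance,
enrichment, and promoter motif/lifespan co-evolution — together with
synthetic-data generators that plant each kind of signal, so the whole chain
is testable end to end without any external download.

It is aimed at comparative genomicists working with species-by-gene
expression compendia (log2 TPM, batch-corrected upstream), species trait
tables, and phylogenies.

## The statistics at the core

**Association.** For each gene *g* with expression x<sub>g</sub> observed in
≥ 10 species, association with log2(MLS) is tested two ways:

- *Spearman rank correlation* ρ(x<sub>g</sub>, log2 MLS), average ranks for
  ties, exact permutation p-value for n ≤ 7 and the t approximation above.
- *Phylogenetic generalized least squares (PGLS)*: x<sub>g</sub> = β₀ + β₁
  log2(MLS) + ε with cov(ε) ∝ V, where V[i,j] is the shared root-to-ancestor
  branch length of species i and j (Brownian motion). β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y,
  with a two-sided t test on β₁ (df = n − 2). The model is fit on every tree
  of an ensemble and the **maximum** p-value across trees is used — a
  conservative treatment of phylogenetic uncertainty.

Multiple testing uses the Benjamini–Krieger–Yekutieli two-stage adaptive
step-up procedure; genes with q < 0.10 are called, signed by the statistic,
and the Spearman and PGLS calls are merged (opposite-sign conflicts dropped).

**Concordance.** Two signed gene sets A and B over a universe of N
investigated genes are compared by counting *concordant* genes
(|A₊∩B₊| + |A₋∩B₋|) and *discordant* genes (|A₊∩B₋| + |A₋∩B₊|) against their
independence expectations E = Σ<sub>s</sub>|A<sub>s</sub>||B<sub>s</sub>|/N.
The summary is an observed-vs-expected odds ratio conditioned on A,
OR = [O/(n<sub>A</sub> − O)] / [E/(n<sub>A</sub> − E)], tested by an exact
two-sided binomial test of O against the chance rate E/n<sub>A</sub>.

**Enrichment.** Fisher's exact test of a query set against GMT annotation
terms over an explicit background, BKY FDR across terms.

**Motif co-evolution.** Promoters (1000 bp upstream) are scanned with
JASPAR-style position weight matrices using log-odds scores whose null
p-values come from an exact dynamic-programming distribution over
discretized scores (both strands, overlapping hits kept, windows with N
skipped, hits at p < 1e-4). Per species, the called gene set is compared to
background genes on two metrics — presence odds ratio and mean-count ratio —
and each metric's per-species series is Spearman-correlated with MLS. A
motif is called co-evolving only if **both** metrics are significant
(BKY FDR < 0.05) in the same direction.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(conditions in `analysis/study.toml`: 29 species, 2000 genes, 200 planted at
expected |ρ| ≈ 0.8, a partner set planted at concordance OR 3, a gain-trend
promoter motif plus a decoy):

```
python analysis/01_simulate.py
python analysis/02_association.py
python analysis/03_concordance.py
python analysis/04_enrichment.py
python analysis/05_motif_coevolution.py
```

Output of a run (seed 7):

```
calls at FDR < 0.10 per method:
  pgls      called= 116  true= 116  observed FDR=0.000
  spearman  called= 231  true= 200  observed FDR=0.134
merged call set: 231 genes, sensitivity 1.000, observed FDR 0.134

concordant observed 35 vs expected 17.3  OR=2.20  p=7.84e-05
discordant observed 16 vs expected 17.3  OR=0.92  p=9.00e-01

motif(s) called as co-evolving with lifespan: ['PLANTED_GAIN']
```

Reading this: PGLS is the conservative branch (fewer calls, none false);
Spearman recovers every planted gene at the cost of an observed FDR near its
nominal 10%. The partner set, planted to agree in sign with the truth genes,
shows roughly twice as many concordant genes as chance predicts (the estimate
is diluted below the planted OR 3 because the query is the *called* set, not
the truth), with discordance at chance level. The planted promoter motif is
recovered on both trend metrics while the decoy is not.

The same pipeline runs from one config via the CLI:

```
lifecon run --config analysis/study.toml
```

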