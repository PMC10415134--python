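# Synthetic cross-species study: 29 mammals, 2000 genes, 200 with expression
# linearly tied to log2 maximum lifespan, a partner gene set planted at
# concordance odds ratio 3, and promoters carrying a gain-trend motif.
seed = 7
out_dir = "results/study"

[stages]
simulate = true
associate = true
concord = true
enrich = true
scan = true
coevolve = true

[simulate]
n_species = 29
n_genes = 2000
n_planted = 200
n_trees = 10
partner_size = 300
promoter_background_genes = 200

[associate]
fdr = 0.10
min_species = 10

[enrich]
fdr = 0.05

[scan]
pthresh = 1e-4

[coevolve]
fdr = 0.05
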