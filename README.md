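# scgpcr

Single-cell GPCR expression profiling from microfluidic qPCR data.

G-protein-coupled receptors (GPCRs) are the largest drug-target family, yet
their expression is usually measured in bulk cDNA, hiding the cell-to-cell
heterogeneity that matters for targeting diseased subpopulations (for
example dedifferentiating vascular smooth muscle cells, or inflamed
endothelium). `scgpcr` is a tested, reusable implementation of the analysis
chain used for single-cell RT-PCR GPCR panels on microfluidic arrays:

1. **Cell-identity gating** — cells are re-classified from the qPCR data
   itself: usable cells must amplify the quality-control reference genes
   (*Gapdh*, *Hprt*), must be negative for a panel of lineage-exclusion
   markers (*Ptprc*, *Itgam*, *Cd4*, *Cd8*, *Cd19*, *Ly6g*, *Cdh1*,
   *Tnni2*) and must amplify exactly one identity marker (*Cdh5* for
   endothelial, *Myh11* for smooth muscle cells). Everything else lands in
   a per-group contamination table.
2. **LoD expression transform** — with the platform limit of detection at
   Ct = 24 cycles, expression = 2^(LoD Ct − sample Ct); entries at or
   beyond the limit (or with no amplification) are 0. Per-gene detection
   frequencies and receptors-per-cell counts summarize heterogeneity.
3. **Clustering** — k-means on the rows of the cell × cell Pearson
   correlation matrix of log2(x+1) profiles (i.e. Euclidean distances *of
   the correlation matrix*), t-SNE maps, and cluster-specific genes by an
   exact binomial test on transcript-count proxies, filtered at fold
   change > 1.5 or < 0.7 versus all cells (raw P < 0.05).
4. **Co-expression networks** — gene–gene Spearman rank correlations with
   the ρ > 0.3 display threshold, exported as TSV edge lists.
5. **Promoter TFBS enrichment** — JASPAR-style PWMs scanned over 1 kb
   promoter windows ([TSS−950, TSS+50)), best hits min–max normalized, and
   gene sets tested against the global promoter background with
   z = (x̄_set − x̄_global)/(s_global/√n); p-values are signed-z-transformed
   for heat-map export.
6. **NanoString normalization** — positive-spike geometric-mean scaling,
   mean + 2 s.d. negative-control background subtraction, the <20 floor
   rule, and a geNorm reference-gene stability screen (M values).
7. **Synthetic data** — every input above can be simulated with planted
   ground truth (subpopulations, contaminants, correlated pairs, motif
   instances, lane scale factors), so the whole pipeline is testable
   without any external downloads.

## Worked example

Simulate 60 smooth-muscle-like cells with 15% planted contaminants, gate,
quantify and cluster them:

```bash
scgpcr simulate cells --n-cells 60 --contamination 0.15 --seed 7 --out demo/sim
scgpcr gate    --ct demo/sim/ct_matrix.csv --panel demo/sim/panel.csv \
               --target smc --out demo/gated
scgpcr express --ct demo/gated/retained_ct.csv --panel demo/sim/panel.csv \
               --out demo/expr
scgpcr cluster --expr demo/expr/expression.csv --k 2 --seed 1 --out demo/clusters
scgpcr network --expr demo/expr/expression.csv --threshold 0.3 --out demo/edges.tsv
```

which prints

```
wrote 60 cells x 177 genes to demo/sim
retained 52 of 60 cells
receptors per cell: 23.5 +/- 0.5 (mean +/- s.e.m.)
2 clusters over 52 cells
80 edges over 177 genes
```

`demo/gated/contamination.tsv` is the identity report (percentages over
cells passing QC, one row per sample group):

```
group   cdh5_only  myh11_only  other_markers  no_marker
all     0.0        86.7        10.0           3.3
```

so 86.7% of usable cells were confirmed single-positive smooth muscle
(these are retained), 10% carried a lineage marker and 3.3% no identity
marker — consistent with the 15% planted contaminant rate. The expression
stage reports each gene's detection frequency (`demo/expr/frequency.tsv`)
and how many of the analyzable (intron-spanning) GPCRs each cell expresses;
the cluster stage emits per-cell labels, a (cluster, gene) marker table
with fold changes and binomial p-values, and a 2-D t-SNE embedding.

The same stages are available as library functions (`scgpcr.gate_cells`,
`scgpcr.lod_transform`, `scgpcr.kmeans_cluster`,
`scgpcr.cluster_marker_genes`, `scgpcr.build_network`,
`scgpcr.score_promoters`, `scgpcr.normalize_lanes`, ...), and
`scgpcr run --config cfg.yaml` drives the full chain from one flat YAML
config with a reproducibility manifest.

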