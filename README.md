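# coexnet

Co-expression module networks for two-group transcriptomics: module
detection, module-level enrichment, eigengene Bayesian networks, consensus
regulator prioritization, and connectivity-score drug repurposing — in one
tested, reusable Python package.

## The problem

Bulk expression cohorts that contrast a reference with a disease state
(for example stable versus unstable, hemorrhage-positive atherosclerotic
plaque segments) carry coordinated transcriptional programs that
single-gene differential tests miss. The workflow implemented here asks,
in order:

1. **Which gene modules co-vary across samples?** Weighted gene
   co-expression network analysis (WGCNA-style): soft-thresholded Pearson
   adjacency `a_ij = |cor(x_i, x_j)|^β`, topological overlap
   `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
   `ℓ_ij = Σ_{u≠i,j} a_iu a_uj`, average-linkage clustering of `1 − TOM`,
   and eigengene (first principal component) merging below a
   dissimilarity threshold of 0.25.
2. **Which modules matter?** Hypergeometric overrepresentation against
   gene-set collections, summarized per module by the cluster enrichment
   score `CES = |log10(best BH-adjusted p)|` (so CES > 3 ⇔ adjusted
   p < 0.001), plus rank-based GSEA on the log2 fold-change ordering,
   Jaccard/hypergeometric partition overlap, Lin semantic similarity over
   a term ontology, and expression-matched signature scoring.
3. **How do the module programs relate?** A directed Bayesian network over
   module eigengenes: Gaussian-BIC hill climbing with restarts, learned on
   bootstrap resamples; arcs are kept by bootstrap strength (default
   0.85 aggregate threshold, 0.7 strength floor). A module-proximity
   statistic reports each module's average adjacency to a focal module,
   normalized so the all-module reference equals 1.
4. **Who regulates the module of interest?** Two independent GRN
   reconstructions — extra-trees importance (GENIE3-style) and mutual
   information with data-processing-inequality pruning (ARACNe-style) —
   are each ranked by weighted node degree into the module; their top-k
   intersection is filtered by a motif-support table (NES ≥ 3) to give
   consensus regulators with provenance.
5. **What might reverse the program?** The weighted connectivity score
   `WTCS = (ES_up − ES_down)/2` (0 when the two running-sum enrichments
   share a sign) of the module's up/down signature against a library of
   drug-induced rankings, normalized per sign onto [−1, 1]; drugs below
   −0.7 are reversal candidates.

Every stage is exercised end-to-end on synthetic data with known ground
truth: genes loading on latent module factors, a linear-Gaussian DAG among
factors, a condition shift on one module, planted regulator effects, and
drug libraries with planted reversers/mimickers/neutrals.

## Worked example

`examples/01_modules_from_synthetic_cohort.py` simulates the reference
conditions (1000 genes, five planted modules of 250–50 genes, 16 + 27
samples, a +2 log2-unit condition shift on module 1), filters, builds the
network at power β = 6, and compares detected with planted modules:

```
simulated 1000 genes x 43 samples
MAD filter retained 750 genes
module sizes: {1: 258, 2: 243, 3: 47, 4: 46}
adjusted Rand index vs planted modules: 0.849
module 1 (n=258): |cor(eigengene, factor 1)| = 0.999
module 2 (n=243): |cor(eigengene, factor 2)| = 0.989
module 3 (n=47): |cor(eigengene, factor 3)| = 0.999
module 4 (n=46): |cor(eigengene, factor 5)| = 0.998
```

The ARI of 0.85 says the detected partition matches the planted one up to
a minority of boundary genes; each detected eigengene tracks its latent
factor almost perfectly (|r| ≥ 0.99). The other examples continue the
story — `02` scores modules (CES 36–88 for the five matched sets, then a
bootstrap eigengene network), `03` recovers exactly the three planted,
motif-supported regulators out of 20 candidates, `04` passes all ten
planted reversers and nothing else at the −0.7 screen, and `05` runs the
whole pipeline through one config:

```
consensus regulators (motif-supported): ['M1G001', 'M1G002', 'M1G003']
drug screen: 10 candidates below -0.7 (classes: ['reverser'])
```

A thin CLI wraps the same stages (`coexnet run-all --workdir out/ --seed 1`;
per-stage subcommands `simulate`, `preprocess`, `wgcna`, `enrich`,
`proximity`, `bn`, `grn`, `score`, `connect`, `report`), writing TSV/GMT
artifacts plus JSON manifests that hash-chain each stage's inputs.

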