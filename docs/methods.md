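# Methods

This note records the models, estimators, defaults, and numerical choices
behind `coexnet`, and what the synthetic-data validation does and does not
establish.

## Synthetic cohort model

The generator (`coexnet.simulate`) draws, per sample, module factors from
a linear-Gaussian structural equation model over module indices:

    z_j = Σ_{k ∈ pa(j)} b_jk z_k + ε_j,   ε_j ~ N(0, σ_z²)

evaluated in topological order of a user-supplied acyclic factor DAG.
Samples in condition B then receive `z_m += δ_m` for each shifted module.
The shift is applied *after* the SEM pass, so it does not propagate to
child factors: the planted differential signal stays confined to the
shifted modules, which keeps the differential-ranking recovery property
well defined. A gene g of module m is

    x_g = λ_g z_m + N(0, σ_g²),   λ_g ~ U(λ_min, λ_max)

with unsigned loadings by default (an unsigned co-expression network
downstream cannot distinguish sign conventions; a random-sign option
exists). Designated regulator genes live in one module; each of their
targets additionally receives `Σ_t w_t x_t` with half-normal weights
`w = |N(0, σ_w)|`. Half-normal rather than signed weights is deliberate:
signed regulator terms can cancel the condition shift in a target, which
would make "every shifted-module gene has a positive log2 fold change"
false by construction rather than by failure of the method. Background
genes are N(0, 1) noise. Finally every gene receives a fixed baseline
intensity drawn from U(4, 12) (log2-microarray scale). Baselines leave
correlations, MADs, and fold changes untouched but make
average-expression bins heterogeneous, which the control-matched
signature score requires; setting `baseline_range=(0, 0)` recovers
exactly factor-proportional module genes.

Defaults mirror the study design at desk scale: 1000 genes, five modules
of 250/200/150/100/50 genes, 16 + 27 samples, factor DAG
1→2, 1→3, 2→4, 3→5 with coefficients 0.6, δ = 2 on module 1 (which also
hosts the five regulators), σ_z = 1, σ_g = 0.3, λ ∈ [0.6, 1]. The DAG
coefficient 0.6 yields inter-module eigengene correlations of ~0.4–0.5,
the moderate coupling typically seen between related modules in real
co-expression data; at 0.4 the eigengene network is essentially
undetectable at n = 43, at 0.8 modules begin to merge.

Gene-set simulation emits one matched set per module (sharing
`overlap_frac` of its genes, padded to the module's size from outside)
plus random decoy sets, under a small rooted term DAG whose leaves are the
sets; information content is `−log` of the propagated annotation
frequency. Drug-profile simulation plants reversers (query-up genes at
the bottom of the ranking, query-down at the top), mimickers (opposite),
and uniform-permutation neutrals, then applies a configurable number of
random transpositions; signed scores fall linearly down each ranking.

**What passing these tests shows — and not.** Recovery on this generator
demonstrates the estimators are correctly implemented and behave as
designed under the model they assume (linear factor structure, Gaussian
noise, no batch effects, no probe-level artifacts, complete data). It
does not establish performance on real microarray or RNA-seq cohorts,
where unmodeled correlation structure, heavy tails, and normalization
residue can degrade every stage.

## Preprocessing

Duplicate transcripts collapse to the row with the highest mean
(ties: earliest input row, so the operation is idempotent and
permutation-stable). The variability filter computes the per-gene median
absolute deviation about the gene median (a mean-centered variant is
available) and removes genes strictly below the first quartile of MADs
under the linear-interpolation quantile convention. Note the filter is a
quantile of its *input* distribution: re-applying it removes a further
quartile; that is inherent to any quantile filter, so the pipeline runs
it exactly once. The differential table uses log2fc = mean(B) − mean(A)
(data already log2), Welch's t-test, and Benjamini–Hochberg adjustment;
an empirical-Bayes moderated t would change p-values slightly but not the
fold-change ranking that downstream GSEA consumes. Ties in log2fc break
lexicographically by gene symbol so the ranking is total.

## Co-expression network

Unsigned adjacency `|cor|^β` (signed variant `((1+cor)/2)^β` behind a
flag); zero-variance genes are removed with a warning. The scale-free fit
index bins positive degrees into 10 equal-width bins and regresses
log10(frequency) on log10(mean degree); the R² is signed by the slope so
positively sloped fits cannot pass. Equal-width (not equal-count) binning
is essential: equal-count bins have constant frequency by construction
and the regression would be undefined. Power selection takes the smallest
candidate whose index reaches 0.8, else the argmax with a warning. On
modular synthetic data no power reaches 0.8 — a few planted factors do
not produce a scale-free degree distribution — so the pipeline default
pins β = 6, the study setting, with the scan available via
`soft_power: null`.

TOM uses the standard unsigned formula with the diagonal excluded from
degrees and `TOM_ii = 1`. Modules come from average-linkage clustering of
`1 − TOM` with a static cut at 0.90 × the maximum merge height; clusters
below 30 genes become unassigned (label 0). The 0.90 factor was chosen
because background genes join the dendrogram at essentially the maximum
height, so cutting at 0.99 × max leaves distinct true modules fused;
recovery on the reference conditions (ARI 0.82–0.95 across seeds)
validates the cut, which remains configurable. Eigengenes are the leading
right singular vector of the gene-standardized module submatrix,
sign-aligned to correlate positively with the module mean and reported
with variance explained; merging repeatedly fuses the closest eigengene
pair while `1 − cor < 0.25`, recomputing eigengenes after every merge,
and relabels by size so the result is independent of input label order.
Module proximity divides each module's mean cross-adjacency to the focal
module by the pooled mean over all non-focal assigned genes; the
reference is exactly 1 by construction and the statistic is invariant to
uniform adjacency scaling.

## Enrichment statistics

Overrepresentation uses the hypergeometric upper tail `P(X ≥ k)` with the
universe equal to all genes surviving preprocessing, BH-adjusted across
sets; CES is `−log10` of the module's best adjusted p (zero p capped at
the float tiny value with a warning). GSEA uses hit increments
`|r|^p / Σ_hits |r|^p` (default p = 1), miss decrements `1/(G−K)`, ES =
maximum deviation from zero, and a gene-label permutation null (default
1000 draws): NES divides ES by the mean |null| of the same sign, and the
p-value is the smoothed same-sign tail. Partition overlap reports Jaccard
and hypergeometric p per module pair over the union of assigned genes.
Semantic similarity defaults to Lin's measure with best-match averaging
(Resnik, normalized by the ontology's maximum IC, behind a flag); pairs
whose only common ancestor is the root score 0. The signature score bins
genes by average expression (24 equal-count bins), samples 100 controls
per signature gene from the *non-signature* members of its bin (falling
back to the whole bin, or sampling with replacement, with warnings), and
reports mean signature minus mean control expression per sample.
Excluding signature genes from control pools departs from the common
single-cell implementation but is required for the score to equal the
planted shift when the signature dominates its expression bin.

## Eigengene Bayesian network

Local scores are Gaussian BIC,
`−n/2 (log 2πσ̂² + 1) − (|pa|+2)/2 log n`, computed from the covariance
matrix with residual variances floored at 1e−12 so near-deterministic
relations stay scorable; the total decomposes over nodes. Hill climbing
is steepest-ascent over add/delete/reverse moves with strict improvement,
lexicographic move order for determinism, and restarts: the first climb
starts empty; the next `n_nodes` restarts start from complete DAGs over
random orders whose sink cycles through every node, pre-pruned by
backward parent selection (this lets greedy deletion uncover collider
structures that single-edge additions cannot reach); further restarts use
sparse random DAGs. An exhaustive enumerator (25 DAGs on 3 nodes, 543 on
4) serves as the test oracle; restarted hill climbing matches its optimum
on 600/600 random small datasets at 20 restarts.

Bootstrap aggregation resamples samples with replacement, learns a DAG
per replicate, and reports per-pair strength (fraction of replicates
containing the edge in either direction) and direction (majority share).
The averaged network keeps pairs with strength ≥ 0.85, oriented by
majority, then drops strength < 0.7 — the bnlearn-style reading of the
two thresholds, chosen because applying 0.85 to direction-aware support
would discard edges whose orientation is genuinely unidentifiable
(support split ~50/50) despite maximal skeleton evidence; a
`mode="directed"` flag provides the other reading. Residual cycles (rare,
since per-replicate DAGs are acyclic) are broken by iteratively dropping
the lowest-support arc in a cycle. Module eigengenes enter the network
only when their CES strictly exceeds 3.

## Regulator prioritization

The tree-ensemble engine fits one extra-trees regressor per target
(default 1000 trees, √(#regulators) candidate features per split — the
method's canonical settings) on all regulators except the target itself
and normalizes importances to sum to 1 per target. The information
engine discretizes each gene into `⌈n^(1/3)⌉` equal-frequency bins and
computes Miller–Madow-corrected mutual information, clipped at zero. The
cube-root rule replaces the more common square-root rule deliberately:
with √n bins the joint table is so sparse that the Miller–Madow
correction cannot remove the plug-in bias, and independent pairs at
n = 1000 score ~0.27 nats; with cube-root bins the null sits at ~0.003
nats. DPI pruning removes, in every fully connected triangle, the
smallest edge when it is below `(1−ε)` times the smaller of the other two
(ε = 0 by default); decisions are made on the original matrix and applied
at the end, so pruning is idempotent, and an exact tie removes the
lexicographically smallest gene pair for determinism. Node degree into
the target module (module-restricted by default; a global variant exists)
ranks regulators; consensus intersects two top-k lists and then requires
motif-table support at NES ≥ 3 for at least one module target,
reporting per-regulator provenance (both ranks, best NES, motif target
count). The regulon subnetwork connects consensus regulators to
motif-supported module genes, weighted by GRN weight, and reports module
coverage. Motif scanning itself is upstream of this package: the motif
table is consumed, never computed.

## Connectivity screen

Each drug profile is a full signed ranking. The single-set enrichment is
the weighted running sum with hit weights ∝ |score| (exponent 1) and
uniform miss decrements; WTCS combines up and down enrichments as
`(ES_up − ES_down)/2` when their signs differ and is 0 otherwise;
one-sided queries use the single ES (negated for down-only queries so
reversal stays negative). Library-wide normalization divides positive
scores by the maximum positive and negative scores by the magnitude of
the minimum — the simplest order-preserving map onto [−1, 1]; cell-line
standardization is out of scope because a single library is screened.
The screen keeps normalized scores strictly below −0.7. Query genes
missing from the library universe are dropped with a warning.

## Orchestration and determinism

All randomness flows from one config seed through fixed per-stage
derivations; every generator and learner is bit-reproducible under a
fixed seed (asserted by tests). Each stage writes a JSON manifest with
parameters, its derived seed, and SHA-256 hashes of inputs and outputs;
dependent stages verify their inputs against the producer's recorded
hashes and fail loudly on tampering or missing upstream artifacts.

## Problem sizes used in tests and acceptance

The suite validates at sizes a single CPU handles in seconds: the
reference 1000-gene cohort for module/differential recovery; a 10-node,
200-sample SEM with 200 bootstrap replicates for the Bayesian network
(skeleton precision ≥ 0.8 at the 0.85/0.7 thresholds); a 20-regulator ×
200-target planted GRN at n = 100 with 50 trees for edge AUROC; a
140-gene two-module cohort for consensus recovery over repeated seeds;
and 100-drug libraries for the screen. The tree count in tests (30–100)
is below the 1000-tree API default; importance rankings for these
problem sizes are already stable at that depth.

## Known limitations

- The static tree cut approximates, but does not reproduce, dynamic
  hybrid tree cutting; agreement with the reference WGCNA implementation
  is validated by recovery, not output equality.
- Gaussian BIC assumes linear relations among eigengenes; strongly
  nonlinear module couplings would be missed.
- DPI prunes genuinely direct but weak edges inside densely co-regulated
  triangles; the pruned AUROC on planted networks (~0.81) reflects that
  intrinsic cost, not an estimator defect.
- The permutation GSEA p-value has resolution 1/(n_perm+1); multi-level
  refinement for very small p is out of scope.
- Missing values are rejected, not imputed; inputs are assumed complete
  after upstream normalization.
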