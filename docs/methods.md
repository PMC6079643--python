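# Methods

This note documents the models, estimators and numerical choices behind
`xylemnet`, and what the synthetic data generator does and does not emulate.

## The data model

The pipeline's central object is a gene × section expression matrix from a
cryosection series through developing wood: consecutive tangential sections
across the cambial zone, pooled into one sample per developmental stage
(cambium → expanding xylem → secondary-cell-wall formation → programmed cell
death → mature xylem), replicated across trees. Sample identifiers encode
replicate tree and position (`T1:03`). Replicate series do not align
section-for-section — each tree contributes its own 14–18 pools — so any
per-section analysis (e.g. domain enrichment) is run within a single tree.

## Preprocessing

**Size factors.** Median-of-ratios normalization: for sample *s*, the factor
is the median over genes of `count[g,s] / geomean(count[g,·])`, computed over
genes with no zero entry (the geometric mean is undefined at zero). If no
such gene exists the computation refuses to proceed unless the caller
explicitly enables a fallback that takes per-gene log-means over positive
entries only.

**Variance-stabilizing transform.** Counts are assumed negative-binomial
with variance `μ + αμ²` (one pooled dispersion α). The closed-form
stabilizer for this family is `t(n) = (2/ln 2)·asinh(√(α·n/sf))`: it is
strictly increasing, `t(0) = 0`, and for `α·n ≫ 1` differences behave as
log2 fold changes (`t(1000) − t(100) ≈ log2 10`, within 2%). When α is not
supplied it is estimated by method of moments — the median over genes of
`max(0, (s² − m)/m²)` on normalized counts — floored at `1e-6`. This is a
deliberate re-implementation rather than a dependency on any particular
RNA-seq package's VST: it is deterministic, testable against the closed
form, and lives on the same "VST > 3" working scale. Absolute transformed
values of any external tool are not reproduced, only the filter logic.

**Expression filter.** A gene is "expressed" iff strictly more than the
threshold (default 3) in at least 2 sections of at least 2 replicate trees.
The inequality is strict, so a gene sitting exactly at 3.0 is dropped.

**Imputation.** A missing interior section is replaced by the arithmetic
mean of the two flanking sections of the same tree. No rule exists for a
missing section at a series end; that case raises an error rather than
guessing.

## Network inference

**Mutual information.** MI is computed in nats from the discretized joint
distribution. The default estimator is equal-frequency (rank-based) binning
with `floor(√n_samples)` bins (7 bins at 51 samples): bin labels are ordinal
ranks times `B/n`, with ties broken by sample order, which makes the
estimate invariant under strictly monotone transforms of either profile and
robust to outliers. For tie-free identical profiles the estimate is exactly
`ln B`. Equal-width binning and an order-3 B-spline soft-binning estimator
(fractional bin membership from a clamped uniform spline basis) are
available as alternatives. Constant profiles get MI 0 against all partners
and are flagged. At ~50 samples the plug-in estimator carries a bias of
roughly `(B−1)²/2n`; CLR removes the shared component of this bias.

**CLR.** The rectified ("mixed") context-likelihood-of-relatedness variant:
per gene *i*, μᵢ and σᵢ are the mean and population SD of its off-diagonal
MI values, `zᵢ(j) = max(0, (MI(i,j) − μᵢ)/σᵢ)` and
`CLR(i,j) = √(zᵢ(j)² + zⱼ(i)²)`. σᵢ = 0 contributes z = 0. CLR is invariant
to adding a constant to every off-diagonal MI entry.

**Threshold selection.** For each candidate threshold the degree
distribution of the thresholded graph (isolated nodes excluded) is binned
into powers of two, converted to a density, and fit by least squares as
`ln P(k) = a − γ·ln k` over occupied bins; the candidate with the highest R²
wins, ties going to the smaller threshold. Fits with fewer than 3 occupied
bins are undefined (2 points always fit a line exactly) and such candidates
are ineligible, as are candidates below 30 edges. The exact scale-freeness
statistic used in the original analysis is unpublished; this R²-of-log-log
scan is this package's documented choice.

**The signed network.** Every pair with CLR ≥ threshold (inclusive) becomes
an edge, annotated with the Pearson correlation of the VST profiles over all
samples of all trees concatenated in sampling order; the sign of r is the
edge sign (r = 0 is assigned '+' and flagged). The default threshold is 5;
3.5 is the preset for building comparably sized networks in cross-species
work (the source analysis quotes both 3.5 and 3 for that purpose; both are
accepted as parameters, no intent is guessed). Downstream topology uses the
largest connected component; ties in size break toward the component with
the lexicographically smallest gene ID.

## Topology

Degree, betweenness (unnormalized shortest-path counts; edge weights
ignored), closeness and average neighbour degree, over the largest
sub-network only. Closeness is stored both as total distance ("farness",
lower = more central) and as the standard normalized inverse `(n−1)/farness`;
ranks are defined on the inverse so that rank 1 is always the most central
gene, with ties sharing the minimum rank. Whether the original ranking meant
smallest or largest total distance is ambiguous; both columns are emitted.

## Clustering and expression domains

Genes passing a variance filter are clustered with Ward linkage on
correlation distance `1 − r` applied directly to the precomputed distance
matrix — Ward's derivation assumes Euclidean input, but this combination is
what common heatmap tooling executes and is kept for fidelity; samples are
clustered with Ward on Euclidean distance. The flat cut uses an explicit
`k` (default 7, mirroring six coherent clusters plus a profile-less pool;
synthetic tests cut at the planted k). The original criterion "variance of
σ > 1" conflates variance and SD; both readings are implemented behind a
flag (`statistic="variance"` is the default; at cutoff 1 they coincide).
The criterion by which "no defined profile" genes were pooled is unspecified
and is not reproduced.

Independently, each gene is assigned to the section(s) whose value is
≥ (1 − tolerance)·max over all sections (default tolerance 4%, inclusive,
value-relative — whether the original 4% was relative to the max or to the
min–max range is unstated; value-relative is the more literal reading and is
the documented choice). Genes whose maximum is not positive are skipped and
reported.

## Enrichment

One-sided over-representation only: for universe N, term K, query n and
overlap k, `p = P(X ≥ k)`, X ~ Hypergeom(N, K, n) — identical to one-sided
Fisher — with Benjamini–Hochberg q-values across the terms of each query.
The universe is the expressed, annotated gene set; gene sets are taken as
given (no ontology-graph propagation). Domain enrichment runs within one
named tree.

## Cross-species conservation

Neighborhoods are first-order: seed plus direct neighbours over edges at or
above the threshold (seeds belong to their own neighborhoods; a neighborhood
threshold may only raise, never lower, the network's build threshold).
`expand` performs one breadth step per call. Orthology may be many-to-many
(gene-family maps); a neighbour counts as conserved if *any* of its
orthologs lies in the candidate seed's neighborhood in the other species
("any" mode; a best-hit-only mode takes the first ortholog in map order).
Neighbours with no ortholog are excluded from the denominator.

The conservation statistic is a hypergeometric tail on the overlap between
the ortholog-mapped neighborhood and the candidate's neighborhood, with the
universe restricted to species-B genes that have an A-ortholog. The original
readout is qualitative (marker genes present/absent in neighborhoods); this
p-value is a package-defined quantification and reports carry a note saying
so. Verdicts: *conserved* if p ≤ α (default 0.05) **or** the overlap is
complete (on small networks the hypergeometric cannot reach significance
even for a perfect match, and complete presence is the strongest form of the
qualitative readout); *untestable* if the seed has no ortholog in the other
network or no neighbour is mappable; otherwise *diverged*. When several
candidate orthologs exist the smallest-p candidate is reported.

## Synthetic data: what it emulates and what it does not

`simulate_series` plants the features the analysis consumes: 3 replicate
trees × 14–18 sections (axis coordinate = rank/(n−1) within each tree, so
replicate series deliberately misalign), gene clusters with Gaussian
expression bumps at cluster-specific axis positions
(`μ(x) = base + amplitude·gain·exp(−(x−peak)²/2w²)`), a noise pool of
position-independent genes, NB counts with one global dispersion
(gamma–Poisson mixture), log-normal library sizes normalized to geometric
mean 1, TF labels, cluster-linked gene sets, and an optionally blanked
section to exercise imputation. Defaults: 600 genes, 6 clusters + noise
pool at fraction 0.2, base 50, amplitude 400 (8× base), peak width 0.1,
dispersion 0.1, library-size CV 0.2. The real study published no effect or
noise sizes, so these are chosen for testability: strong enough that the
planted partition is recoverable (variance filtering removes essentially
the whole noise pool and Ward/correlation clustering reaches ARI ≈ 1), yet
with realistic count noise. What is *not* emulated: read-level artefacts,
batch effects, seasonal/latewood biology, gene-length or GC biases, and the
20k-gene scale of real data — passing tests demonstrate the correctness of
the machinery on structure-bearing data, not biological performance on a
real transcriptome.

`simulate_species_pair` plants hub modules (seed + targets sharing a latent
bump, independent NB noise) in two pseudo-species with a 1:1 index-based
ortholog map (optionally thinned), rewiring the targets of a configurable
number of hubs in species B. The two-species study condition used by the
tests and the acceptance script is 500 genes, 5 hubs × 8 targets, amplitude
1600 (32× base), dispersion 0.05, width 0.1, with networks built and
compared at threshold 3.5. This operating point follows from the CLR score
ceiling for a hub with k strong partners among N genes — z is bounded near
`√((N−k)/k)` because the partners themselves inflate the row background —
so small modules in a larger background (k = 8, N = 500) are required for
planted edges to clear the background tail; at the scan-selected threshold
the planted seed–target edges are recovered with precision and recall
≥ 0.8, and the conservation test flags exactly the rewired hub.

## Problem sizes and reproducibility

Default analyses run on 500–600 genes × ~50 sections; MI/CLR is vectorized
(binned joint histograms via flat `bincount`) and a full default run takes
seconds on one CPU. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration and inputs reproduce
every output file byte-for-byte. Headline counts of the original
20k-gene analysis (expressed genes, largest-component size, σ-filtered
count) depend on the archived sequencing data and are out of scope; the
pipeline reports the corresponding quantities for whatever data it is given.

## Known limitations

- The MI estimator's bias at ~50 samples limits edge power; CLR mitigates
  but does not remove it. Hub neighborhoods at high thresholds are
  conservative (high precision, moderate recall).
- Ward-on-correlation-distance is a pragmatic, field-standard abuse of
  Ward's Euclidean assumption; dendrogram heights are not variance
  decompositions.
- The scale-freeness scan assumes the candidate grid brackets a regime where
  the graph is plausibly power-law; on strongly modular (clique-like) data
  the R² criterion can prefer thresholds that isolate hubs.
- The conservation p-value treats neighborhoods as unordered sets; edge
  signs and scores do not enter the statistic.
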