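# Methods

This note records the statistical and algorithmic choices behind each stage,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Enrichment

The test is the one-sided (over-representation) Fisher's exact test: under
the null that the query list is an unbiased draw from the background, the
count k of query genes annotated to a theme is hypergeometric, and the
p-value is the upper tail P(X ≥ k). Enrichment semantics force the greater
tail; a two-sided test would also flag depletion, which is not the question
the tool answers. The tail is evaluated through the hypergeometric survival
function, which works in log-space and is stable for the background sizes
(10²–10⁴ genes) the tool targets; the test suite checks it against exact
rational arithmetic on every contingency table with N ≤ 30.

The background defaults to the *annotation universe* — every gene carrying
at least one theme — rather than an unstated "whole genome", because the
test is only defined over genes that could have been annotated; an explicit
background list can be supplied and is intersected with the universe.
Query genes outside the background are removed from n and reported, never
silently retained, since keeping them deflates every p-value.

Only themes with k ≥ 1 are tested, and the correction's m counts tested
themes (the `m_mode="all"` flag instead counts every theme, padding the
untested ones at p = 1). Corrections implement the textbook formulas —
Bonferroni min(1, mp); Holm step-down running maximum of (m−j+1)p₍ⱼ₎; BH
step-up running minimum of m·p₍ⱼ₎/j — via statsmodels. The default is BH at
α = 0.05, flagged as significant when adjusted p ≤ α (boundary inclusive).
Results sort by adjusted p, ties by theme id, so output order is total and
reproducible.

## PPI confidence classes

Evidence is deduplicated on (canonical pair, method id, pmid, source db);
self-interactions are quarantined before classification because the
topology stage assumes a simple graph. Method identity is plain string
equality on the method id — no ontology-hierarchy reasoning — so two ids
always count as two methods; users whose tables mix granularities should
normalise ids upstream. The direct-capable method whitelist ships as
editable package data (`data/direct_methods.tsv`) listing common
direct-detection method tags (yeast two-hybrid, FRET, AFM and relatives);
it is a starting point, not an exhaustive curation. Classification is
monotone: adding evidence can only promote a pair, a property the suite
checks by randomised perturbation.

## Topology

Only the largest connected component of the direct-physical graph is
analysed; size ties break to the component containing the lexicographically
smallest node id. Betweenness is computed by Brandes' algorithm (networkx,
unnormalized): undirected, endpoints excluded, each unordered source–target
pair counted once, fractional credit across equal-length shortest paths.
The convention is stated because hubs/bottlenecks consume only the *ranking*,
which every consistent convention preserves on a connected graph.

Hub/bottleneck cutoffs use k = ceil(fraction · N) (so a non-empty set for
any non-empty graph) and are tie-inclusive: every node whose value equals
the k-th ranked value is flagged, which can push the set above the nominal
10% but avoids arbitrary exclusion among equals.

## Compound unification and bioactivity

An InChIKey is validated purely by shape (14 uppercase letters, hyphen, 10
uppercase letters, hyphen, one uppercase letter); the proton/flag characters
are never interpreted. Grouping by the first block unifies stereoisomers,
salts and protonation states into one chemical entity, which is the right
granularity for target annotation but deliberately blind to stereochemistry
— a documented trade-off, not an oversight.

The activity filter requires confidence_score ≥ 4, assay type 'B',
target 'SINGLE PROTEIN', and a standard type among IC50/Kd/Ki with value
≤ 10 000 nM; both numeric boundaries are inclusive, and values must already
be in nM (rows in other units are out of contract). "At least one
qualifying value" is read per-record, then per-edge: an edge qualifies if
any of its records does, which is order-independent. The edge's
best_activity is the minimum (most potent) surviving value across group
members, on the view that one chemical entity is represented by its
strongest measured binding. Curated drug-annotation pairs (DrugBank-style)
carry no value and are never subject to the activity threshold, which is
scoped to assay-backed edges only.

## Orthology

Mutual best hits on e-value, threshold 1e-3 inclusive. Ties for best hit
disqualify the gene entirely: "best" is undefined under ties, and a false
orthologue assignment propagates into every downstream conversion, so
omission is the safer error. MBH output is a matching (one-to-one), hence
list conversion can never merge two genes. Bit-score ranking would be a
defensible alternative; e-value minimum was chosen as the criterion the
threshold is already stated in.

## Heatmap clustering

Distances between 0/1 association profiles are Euclidean (√Hamming for
binary rows). Clustering is unweighted average linkage (UPGMA): the
distance between clusters is the size-weighted mean of original leaf-pair
distances, maintained by the Lance–Williams update. It is implemented
in-package because two details are part of the output contract and not
guaranteed by library implementations: ties break deterministically to the
smallest (min-leaf-index, min-leaf-index) cluster pair, and the leaf order
keeps the lower-index cluster on the left, so results are identical across
runs and platforms. Merge heights are verified against both a from-scratch
recomputation oracle and scipy's linkage on tie-free matrices. The Newick
export places each merge's children at half the merge height (ultrametric).
Rows (genes) are clustered; columns can be clustered by passing the
transposed matrix, but are not by default.

## Composite network

One-hop semantics: an edge enters the network iff at least one endpoint is
a query gene, and query genes are always retained even when isolated, since
the display anchors on the user's list. PPI edges are restricted to the
high-confidence direct-physical class. Directions: miRNA→gene and
TF→target; PPI and PCI are undirected and stored in canonical pair order.
Edges are keyed by (pair, type), so the same gene pair can carry a PPI and
a TF edge simultaneously and rebuilding from the same inputs is idempotent.

## Synthetic data

The generator emulates table *shapes* and planted *decision structure*, not
biological realism: theme sizes are uniform (5–12 genes), the PPI graph is
Erdős–Rényi (no scale-free degree law), e-values and activity values are
placed to exercise thresholds rather than drawn from empirical
distributions. Defaults (60 genes, 10 themes, foreground of 15 with 80% of
it drawn from the planted theme, PPI density 0.08, half of high-confidence
pairs direct, 8 planted orthologue pairs, 20 compounds over 12 skeletons)
are sized so each stage has non-trivial positive and negative cases while
the full suite runs in seconds. Every filter boundary is always planted
exactly (score 4, 10 000 nM, Barcode 0.5, e-value 1e-3), so inclusive
semantics are pinned by data, not only by unit tests. Consequently, passing
tests demonstrate correctness of the decision rules and numerics — not that
the defaults are well-calibrated for any real interactome or compound
library. A single integer seed drives one generator stream; bundles are
byte-identical across runs.

The null-simulation check draws 1000 uniformly random foreground lists and
measures how often any theme is BH-significant at α = 0.05; with all nulls
true, BH's false discovery control bounds this family-wise rate by α, and
the discreteness of Fisher's test makes it conservative in practice
(observed ≈ 0.02).

## Problem sizes and numerical tolerances

Oracle sweeps use: all contingency tables with N ≤ 30 (exhaustive,
agreement to 1e-12), 1000 random p-vectors with m ≤ 50, 200 random
connected graphs with ≤ 12 nodes for betweenness (1e-9), and 100 random
distance matrices with ≤ 8 leaves for UPGMA (1e-9) — sizes at which the
brute-force oracles are themselves trivially correct and fast.

## Limitations

- Identifier matching is exact and case-sensitive; no id translation.
- No PSI-MI XML / SDF / miRBase parsing — plain TSV only.
- No weighted or directed centralities; no approximate betweenness for very
  large graphs.
- No GSEA-style ranked enrichment; no theme-redundancy pruning.
- Orthology is strictly pairwise one-to-one; many-to-many orthologue groups
  are out of scope.
- The activity filter assumes pre-converted nM values.
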