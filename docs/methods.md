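# Methods

## Expression input and preprocessing

The unit of analysis is a genes × conditions real matrix with optional
per-sample class labels (normal / disease), read from a tab-delimited
file. Values are used as-is — normalization and log transformation are
assumed to have happened upstream — with an optional `log2(x+1)` flag
for convenience. Preprocessing removes rows with empty or
whitespace-only gene IDs, rows containing unparseable value cells, and
rows whose values are all missing; duplicate gene IDs are collapsed to
the row with the fewest missing values (ties: first occurrence).
Partially missing rows are kept; every downstream similarity is
computed over pairwise-complete positions. Preprocessing is idempotent
and never changes the sample dimension. Sample classes are never
inferred from sample names; they come from a sidecar TSV.

## Expression similarity

The co-expression notion is pattern similarity under affine
transforms: two profiles are maximally similar when one is
`a·x + b` of the other with `a ≠ 0`, including negative scaling. The
default measure is the absolute Pearson correlation over
pairwise-complete positions, clamped to [0, 1]; it is exactly 1 for
any noise-free affine relation and degrades monotonically in expected
value with added Gaussian noise. Absolute Spearman is provided as a
rank-based robust alternative, and the measure is a pluggable strategy
(any symmetric function into [0, 1] works). Whether a pattern
similarity should treat negative scaling as similarity is a modelling
choice; this package takes the absolute value, since an inverted
profile is still an affine image of the pattern. Constant profiles and
pairs with fewer than two complete positions get an *undefined* (NaN)
score, which never produces an edge — defining them as 1 would create
spurious hubs out of flat genes, and 0 would silently assert
dissimilarity that was never measured.

The full matrix is a pure function of (values, measure): a vectorized
centered-dot-product fast path handles complete data, and a pairwise
loop handles missing values; the two paths are tested against each
other and against an independent per-pair oracle. For an array of
n genes the all-vs-all cost is n² ordered evaluations
(`n_pair_evaluations`), reported so users can gauge the cost of large
runs; the matrix itself computes each unordered pair once.
Chunked/parallel execution can be layered on top of the pure function;
none is built in.

## Module extraction by threshold decrement

The CEN at threshold δ has an edge for every pair with similarity ≥ δ
(inclusive). δ sweeps from `delta_start = 0.9` down to
`delta_end = 0.5` in steps of `alpha = 0.1` — five network
generations; α is configurable, 0.1 being the coarsest decrement that
visits {0.9, 0.8, 0.7, 0.6, 0.5}. At each δ, on the subgraph induced
by genes not yet assigned:

* **Core selection** picks the unassigned gene of maximum degree,
  provided that degree reaches the minimum neighborhood threshold
  `rho = 3`; ties break to the lexicographically smallest gene ID so
  the procedure is deterministic.
* **Growth** takes the connected component containing the core.
  Multi-hop membership is intended: the border-gene notion concerns
  neighbors of non-core members, which only exist if membership
  extends beyond the core's direct neighborhood.
* **Border marking** flags members with degree < ρ.

This repeats until no core qualifies, then δ decrements. Degrees are
counted on the unassigned-restricted graph by default (a module cannot
recruit assigned genes, so edges to them are inert); `degree_scope="full"`
switches to whole-network degrees. Modules are pairwise disjoint,
genes assigned at a higher δ never move, every extraction records its
δ and a degree snapshot, and genes never assigned by `delta_end`
are reported as unassigned rather than forced into a leftover module.
The similarity matrix is computed once; only the threshold changes
between generations.

`ThresholdDecrementExtractor` wraps this as a scikit-learn clusterer
(`fit`/`fit_predict`, `labels_` with −1 for unassigned, `modules_`,
`border_pool_`), accepting either an expression matrix or, with
`measure="precomputed"`, a similarity matrix.

## GO semantics

The ontology reader keeps `is_a` edges only (a `part_of` flag exists),
drops obsolete terms, partitions namespaces, and rejects cyclic input.
Annotations (GAF 2.x or two-column TSV) are propagated to all
ancestors (true-path rule); the corpus is the set of genes with at
least one annotation in the chosen namespace — Biological Process for
the prioritization pipeline. Information content is
`Ic(t) = −log2(term_count(t)/corpus_size)` — bits; the base only
rescales Ic and cancels in Lin similarity — with `Ic(root) = 0` and
terms annotating no corpus gene treated as undefined. Lin term
similarity is `2·Ic(MICA)/(Ic(t1)+Ic(t2))`, where MICA is the common
ancestor of maximal Ic; a root–root pair is 0 by convention.
Gene-level similarity combines the two genes' direct term sets by
best-match average (the convention of the widely used GOSemSim
implementation); a max rule is available. Evidence codes are kept by
default with an IEA-exclusion flag.

## Border-gene prioritization

Border genes pooled across modules are ranked by the pooled sample
variance across all samples (ddof 1). The phrase "differentially
expressed genes with highest variance between normal and disease
samples" admits a second reading — absolute class-mean difference —
which is implemented behind `de_stat="meandiff"`; pooled variance is
the default ranking statistic. The top `k = 2000` (clamped to the pool
with a warning) pass to the semantic stage, optionally through a
two-column ID mapping (one-to-many keeps the first target, with a
warning). β is the mean of the defined off-diagonal semantic scores; a
gene is *interesting* if it participates in ≥ 1 pair scoring ≥ β
(inclusive, with a 1e-12 tie tolerance) — the most inclusive
deterministic reading; a stricter row-mean rule is available.
Undefined scores are excluded from both β and selection.

## Enrichment

Per-module GO enrichment uses the exact hypergeometric upper tail
P[X ≥ hits] (no normal approximation; scipy's survival function,
cross-checked in tests against direct combinatorial enumeration). The
population is the annotated corpus of the namespace, not all genes on
the array — web enrichment tools hide this choice; it is explicit
here. q-values are Benjamini–Hochberg, adjusted within one module's
family of tested terms, matching how per-module FDR tables are usually
presented. Term membership uses propagated annotations.

## Synthetic data

The generators produce exactly the structure the method assumes, so
ground truth is known by construction:

* **Planted modules** (`generate_expression`): per module a base
  profile ~ N(0,1) over 28 samples (14 per class); members are
  `a·(base + d·disease) + c` with per-gene scale `a` of magnitude
  0.5–2 and random sign, shift `c` in ±2, plus optional N(0, σ²)
  noise (default σ = 0). The class shift `d` enters through the shared
  base, so noise-free members stay exact affine transforms of each
  other. Background genes are i.i.d. N(0,1); 30% get a ±1 class-mean
  shift. One noise-SD is a moderate, realistic effect size; a much
  larger shared shift would make "background" genes strongly mutually
  correlated through the class indicator, contradicting their role as
  unstructured background.
* **Border scenarios** (`generate_border_scenario`): a similarity
  matrix is *designed* (hub + ρ-member clique at 0.93, border gene i
  attached to exactly i members, non-edges at 0.80 — correlation
  geometry forbids small values between near-collinear profiles),
  projected to the nearest correlation matrix, verified to preserve
  the designed δ = 0.9 graph (feasible for ρ ≤ 4), and realized
  *exactly* as sample correlations by factoring the target against a
  mean-zero orthonormal basis. Expected roles follow from the designed
  degrees, independent of the extractor.
* **Toy ontology** (`generate_toy_ontology`,
  `generate_prioritization_study`): a BP root with one subtree per
  module; members annotated to subtree leaves, background to the root.
  The prioritization study annotates module-1 borders coherently and
  module-2 borders to the root only, making the expected interesting
  set known a priori. Border profiles are scaled (×3) to dominate the
  variance ranking — scaling changes variance, never correlations.

What these generators do **not** emulate: probe-level artifacts,
background correction, intensity-dependent noise, realistic GO
topology or annotation depth. Passing tests demonstrate the
algorithmic contracts (recovery of structure the model assumes), not
performance on real arrays.

With 28 samples, random background correlations occasionally (≈2% of
seeds) clear the lowest threshold 0.5 for three mutual neighbors,
producing a small spurious background module. Planted-module recovery
is therefore measured as the adjusted Rand index over planted-module
genes; the planted modules themselves are recovered exactly at
δ = 0.9 for essentially all seeds.

## Numerical and design notes

* Scores are clamped to [0, 1]; the 1e-12 affine-invariance tolerance
  covers floating-point rounding in the correlation.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of its spec and seed, and the pipeline
  is bit-reproducible given (inputs, config, seed).
* Whether core-selection degrees should count edges to already
  assigned genes is ambiguous; both behaviors exist
  (`degree_scope`), defaulting to unassigned-only.
* Problem sizes in the test-suite and acceptance runs (tens of genes,
  28 samples, 2000-draw null simulations, 100 random oracle fixtures)
  are chosen to exercise every code path while keeping the whole suite
  interactive-fast; all scale linearly or quadratically to real
  studies.

## Known limitations

* The exact similarity measure of the original pattern-similarity
  literature is approximated by its defining invariances (abs-Pearson
  satisfies them all); if a different realization is wanted it can be
  plugged in without touching the extractor.
* No overlapping or fuzzy module membership; no soft thresholding.
* Gene-ID translation is file-based; no online lookups.
* Counts reported for real disease datasets in the literature (e.g.
  interesting-gene totals for a specific Alzheimer cohort) depend on
  era-specific GO releases, annotation databases and mapping tables
  and are not reproduction targets for this package.
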