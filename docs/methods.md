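# Methods

This note records the models and procedures implemented in `epicart`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. No empirical claim is made here that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The pipeline's universal input is a gene × sample matrix of log₁₀
expression values with an optional sample → class assignment. On the log₁₀
scale a difference of 1 corresponds to a ten-fold linear change; all
effects, weights and propagated signals respect this convention. Input is
assumed to be preprocessed, gene-level (or probe-level, taken as given)
log₁₀ data; raw microarray/count preprocessing is out of scope. An optional
`log10_transform(x, epsilon=1)` exists for linear-scale input.

Gene-wise centering (`center_genes`) subtracts each gene's mean across all
samples of the loaded cohort, so the map portrays *differential* expression
relative to the cohort mean. Centering is applied cohort-wide, not
class-wise, and is idempotent and difference-preserving.

## Self-organizing map

Classic online Kohonen training over gene profiles (observations = genes,
features = samples):

- Grid: rectangular, default 20 × 20, row-major 0-based unit indexing with
  row 0 at top (shared by all modules). 20 × 20 suits cohorts of roughly
  10³–10⁴ genes (2–25 genes per unit).
- Initialization: metagenes drawn uniformly at random from the gene
  profiles (seeded). PCA-plane initialization was considered and not
  needed at this scale.
- Schedules: learning rate 0.5 → 0.01 and neighborhood radius
  max(rows, cols)/2 → 0.5, both decaying exponentially per presentation
  step over 20 epochs; presentation order reshuffled per epoch from the
  seeded stream. These are standard Kohonen settings; nothing in the
  analysis depends delicately on them (the recovery tests pass across
  seeds).
- Final assignment: each gene's BMU under the *final* metagenes, which
  makes the assignment a fixed point of `predict`.
- Ties in BMU search break to the lowest row-major index.
- Determinism: one integer seed drives initialization and presentation
  order; two runs agree bit-wise.

`quantization_error_` (mean Euclidean distance of profiles to their BMU) is
reported for diagnostics.

## Overexpression spots

Per sample portrait, units at or above the portrait's *q*-quantile
(default *q* = 0.98) are *marked*. The quantile is the lower empirical
quantile (type 1, inverse CDF) and ties at the cut are included — stated
because marked-unit counts depend on it. The summary map is the fraction
of portraits marking each unit; the binary map is the union of marks.

Detection segments 8-connected components (≥ `min_size` = 4 units) and
labels them A, B, … by decreasing peak summary value. Components are *not*
extracted from the raw union of marks: a unit enters detection only if it
is recurrently marked. With class labels available (the default in the
pipeline), a unit is kept when at least half of some class's portraits
mark it — this operationalizes a spot as a cluster *overexpressed in a
certain sample class*, and it is what separates two adjacent class-specific
spots whose low-support bridge units would otherwise join them into one
component. Without labels, a unit must be marked by ≥ 5% of all portraits,
which removes single-sample noise marks. Both filters are parameters
(`class_majority`, `min_support`); setting them to 0 segments the raw
union.

A spot is associated with the classes whose class-portrait mean over the
spot's units is positive and within 90% of the maximal class mean.

## Segmentation and enrichment

The grid is partitioned into a central zone Z — the centered rectangle of
side ⌈*f*·dim⌉ per dimension, default *f* = 1/3 — and four corner
quadrants of the remainder: Q1 top-left, Q2 top-right, Q3 bottom-right,
Q4 bottom-left. The quadrant lettering is a declared convention (any
rotation would be equally valid); real maps have fuzzy region borders, so
the crisp partition is an operationalization for counting. Genes in
low-variance ("invariant") units — metagene variance at or below the 0.25
quantile of unit variances — can be counted under a separate `Inv` class.

Overrepresentation of an annotated gene group in a region or in the spots
uses the one-sided (greater) Fisher exact test; the p-value is the upper
hypergeometric tail P(X ≥ overlap), X ~ Hypergeom(universe, annotated,
region). The direction is one-sided because enrichment is a directional
claim. The implementation is cross-checked in the tests against an exact
integer enumeration of the hypergeometric distribution (all tables with
universe ≤ 25) and against an independent log-gamma enumeration for all
tables with universe ≤ 60 in the acceptance script.

The packaged `table1_modifiers.tsv` transcribes a published overview of
chromatin modifiers (symbol, targeted mark H3K4/H3K9/H3K27/H3K36/H3K79/DNA,
writer/eraser/reader role, expected transcription effect) for region
counting and enrichment demonstrations. One reader-and-eraser enzyme
(MBD2) appears as two rows because roles are single-valued here.

## Shrinkage t-test

Per gene (or per spot mean-gene profile): *d* = mean(a) − mean(b), pooled
equal-variance standard error *s*, and *t* = *d* / (*s* + *s*₀). The fudge
*s*₀ is the median of the gene-wise standard errors (a 90%-quantile rule
and explicit numeric values are selectable); it stabilizes small-variance
genes at the price of conservatism. Two-sided p-values use the Student
reference with nₐ + n_b − 2 degrees of freedom, plus a Benjamini–Hochberg
FDR column. Consequences worth stating:

- *s*₀ = 0 recovers the ordinary pooled two-sample *t* exactly; that
  setting, and only that setting, is calibrated (Monte-Carlo type-I error
  ≈ 0.05 at α = 0.05 in the tests).
- With *s*₀ > 0, |t| shrinks for every gene and the Student p-values are
  conservative by construction.
- Genes with zero variance and *s*₀ = 0 get an infinite statistic, p = 0,
  and a warning flag.

The exact shrinkage estimator of the original cartography software is
specified only by citation; the additive median fudge implemented here is
the canonical variant of that family and is recorded in output metadata.

Unit-level significance maps combine the p-values of a unit's genes by
Fisher's method (−2Σln p against χ² with 2k df); the aggregation rule for
significance maps was open and this choice is declared. Empty units carry
NaN.

## wTO spot network

Adjacency = signed Pearson correlation of spot mean-expression profiles
across all samples (soft-threshold exponent β selectable, default 1). The
signed weighted topological overlap keeps signs in the numerator and uses
magnitudes for node strengths:

    w_ij = (Σ_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 − |a_ij|),
    k_i = Σ_{k≠i} |a_ik|,   w_ii = 1.

Magnitude-only wTO cannot distinguish correlation from anti-correlation
networks; the signed variant can, which is the point of the positive/
negative edge split at |w| > τ (default τ = 0.3). The formula is declared
and oracle-tested (brute-force triple loop), not claimed identical to any
particular earlier variant. A useful checked identity: flipping the sign
of one node's correlations conjugates w (w → DwD), swapping exactly that
node's edges between the positive and negative sets. Note that a *global*
sign flip does not negate w — the quadratic numerator term is invariant —
so positive and negative edge sets are not mirror images.

## Pathway signal flow

Pathways are directed graphs over gene, compound, input and output nodes;
edges are activations or inhibitions. Substrate–enzyme–product reactions
convert to one-directional relations (S→E, E→P, both activations);
reversible reactions must be oriented along the intended cycle direction
first. A cyclic pathway is linearized by splitting a designated node into
`X__in` (keeps outgoing edges) and `X__out` (keeps incoming edges); the
result must be acyclic and has exactly one extra node. The packaged
`tca_toy.tsv` is an 8-compound/8-enzyme cycle split at Oxaloacetate into a
17-node chain.

Weights: gene nodes carry 10^(mean log₁₀ fold change of their member genes,
target vs. reference); compounds, inputs and outputs carry 1 because they
have no transcript (post-translational regulation is ignored by
construction). The reference group defaults to the control class.

Propagation processes nodes in topological order: inputs emit their own
weight; every other node aggregates one contribution per incoming edge —
the upstream signal for activation, its reciprocal for inhibition — by the
arithmetic mean (min and product selectable), then multiplies by its own
weight. The exact combination rule of the original PSF software is not
restated in the sources this package draws on; the rule here is declared,
recorded in output metadata, and has the same qualitative behavior (chains
multiply, inhibitions invert, identities: unit weights → unit signals,
reciprocal weights → negated log signals, monotonicity on activation
graphs). Signals are reported in linear and log₁₀ scale for every node.
Per-class mean fold changes are the default; per-sample propagation is
available through the same functions.

## Synthetic cohorts

`generate_cohort` plants disjoint gene modules into a baseline matrix:
entry = baseline + effect·1[gene ∈ module ∧ class(sample) ∈ up-classes]
+ N(0, noise_sd), everything on the log₁₀ scale (Gaussian additive noise on
log expression). The default design is 2000 genes, five classes of 12
samples, four 50-gene modules each up by 1.0 log₁₀ units (ten-fold) in one
class, noise 0.3, baseline 2.0; the fifth class carries no module and acts
as the control. Effect and noise levels are calibration choices of this
package — the sources give none — chosen as a clearly-expressed module
(effect/noise ≈ 3.3) at desk scale; the baseline cancels under centering.
A nine-class variant (`lymphoma_like_design`) mirrors a five-subtype plus
four-control cohort layout with pan-tumor and subtype-specific modules.

What the generator emulates: class-structured co-overexpression, the
log-scale noise floor, disjoint module membership, a control class. What it
does not: probe-level redundancy, batch effects, count-based noise,
correlated backgrounds, unbalanced class sizes (available by design but not
defaulted), fuzzy module membership. Passing recovery tests therefore show
that the pipeline finds clean planted structure at realistic effect sizes —
not that it resolves the fuzzier overlaps of real cohorts.

`generate_toy_pathway` builds the alternating compound/enzyme cycle with a
companion matrix encoding per-enzyme fold changes exactly (reference
samples at 0, target samples at log₁₀ weight, no noise).

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate/load → center → train → spots → counts/
enrichment → per-class shrinkage t and spot t → wTO network → PSF, writing
per-stage TSVs plus `report.json` and `provenance.yaml`. One config seed
drives the generator, the SOM and every derived contrast; `report.json` is
byte-identical across runs with the same config and seed (keys sorted, no
timestamps). In simulation mode the annotated group for enrichment
defaults to the planted module genes, and the toy pathway's enzymes are
mapped onto the first planted module so that pathway activity is coupled
to the class structure.

Problem sizes used throughout the tests and the acceptance script — the
default design (2000 × 60, 20 × 20 grid, 20 epochs, a few seconds per
training), 10⁴ null genes for calibration, 100 random 6-node wTO instances,
all Fisher tables to universe 60 — were chosen so the whole suite runs in
well under a minute of compute per stage on one CPU while still exercising
every code path at realistic scale.

## Known limitations

- The SOM is a single-resolution rectangular lattice; no toroidal
  topology, batch training or GPU path.
- Spot detection assumes overexpression; underexpression spots are not
  extracted.
- The crisp Q1–Q4/Z partition and the 90% class-association rule are
  conventions; real map regions are fuzzy.
- Shrinkage-t p-values are conservative for s₀ > 0; no permutation or
  empirical-Bayes alternative is provided.
- wTO is computed at the spot level only (no gene-level network), with
  β = 1 adjacency by default.
- PSF significance (bootstrap over samples) is not implemented; reported
  signals are point values.
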