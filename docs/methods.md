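# Methods

## Problem and model

`sseforest` predicts the deepest SCOP level shared by a *target* protein
domain and a *template* domain of known classification, from a fixed-length
numeric comparison of the two structures. The five possible outcomes are
CL, FO, SF, FA (same Class, Fold, Super-family or Family) and NA (no shared
level). Because a target can be paired with many templates, these pairwise
predictions are then combined by a set of probability rules to propose a
classification — including for chains that SCOP has not yet assigned, or
that sit in one of its four "Not a true class" place-holder classes.

The two domains must contain the same number N of secondary structure
elements (SSEs); SSEs and SSE pairs are matched by sequential N→C index
("structurally equivalent" pairs). Classification is done by a random
forest over the pair's descriptor vector.

## Descriptors

Per SSE (from the Cα trace and per-residue DSSP annotations):

* **centroid** — unweighted mean of Cα positions (Å);
* **axis** — unit vector from the first to the last Cα;
* **accessibility** — *sum* of per-residue solvent accessibility (Å²).
  Summing (rather than averaging) preserves a length signal; a mean is
  available via `accessibility_mode="mean"`;
* **length** — residue count;
* **type** — binary, 0 for an α-helix, 1 otherwise.

Per SSE pair within a domain: centroid–centroid **distance** (Å) and the
**inter-axis angle**, computed as arccos of the clamped dot product of the
two N→C unit axes and therefore in [0, 180] degrees. No fold-over to
[0, 90] is applied: antiparallel versus parallel packing is structurally
meaningful. RMS angle differences use plain arithmetic differences in
degrees; no circular statistics are needed on the folded range.

The pair feature vector (layout `v1`, M = 2N(N−1) + 6N + 5; M = 35 for
N = 3) stores, in order: both domains' raw distance/angle values per SSE
pair, both domains' accessibility/length/type per SSE, the four RMS
differences over structurally equivalent entries (distances, angles,
accessibilities, lengths), and the sequence identity of the pair. The
layout is versioned and serialized next to every feature table, so
alternative layouts (e.g. difference-only) can be introduced without
breaking stored models.

**Sequence identity** is computed from a global alignment (BLOSUM62,
gap open −11, gap extension −1) as identical columns divided by alignment
length including gap columns. Domain pairs with identity ≥ 0.35 are
discarded (strict "below 35%"), so the classifier sees remote homologs
only.

## SSE segmentation

Maximal runs of helix codes of at least 4 residues become helices; maximal
runs of `E` of at least 3 residues become strands; shorter runs and all
other codes are coil and produce no SSE. By default only DSSP `H` counts
as helix; `{H, G, I}` can be enabled where 3₁₀/π helices should count
toward the 4-residue rule. Runs also break at non-contiguous residue
ordinals (chain breaks), which makes segmentation idempotent on its own
output. Residues without a Cα are dropped before segmentation; alternate
locations resolve to the highest-occupancy Cα.

## Random forest

The forest is implemented in this package rather than delegated, because
its prediction semantics are the point: T = 10 unpruned trees, each grown
on a bootstrap sample of size n (with replacement). At every node,
m = max(1, ⌊log₂(M + 1)⌋) features are drawn without replacement and the
best split by information gain (Gini available by configuration) over
candidate thresholds — midpoints between consecutive distinct values — is
taken. Recursion stops only at pure nodes or when no sampled feature
improves impurity (gain ≤ 10⁻¹²), e.g. identical rows with mixed labels;
there is no depth cap and no minimum leaf size. Leaves store raw class
counts.

A prediction routes the query down each tree and averages the T leaf
class-*ratio* distributions; the label is the argmax, with ties broken by
the fixed class order (CL, FO, SF, FA, NA). The averaged probability p of
the predicted level drives all downstream decision rules. Out-of-bag
accuracy is computed during training as a diagnostic but used by nothing.

All randomness flows from a single integer seed through
`numpy.random.Generator`; per-tree generators are derived from seeds drawn
below 2³¹, making models bit-for-bit reproducible (serialized model JSON
compares equal across runs).

## Benchmark strategies and metrics

Four train/test strategies are built from the pair sets of two consecutive
SCOP releases, with pair identity across releases keyed by the unordered
sid pair: (1) train on all earlier-release pairs, test on later-release
pairs absent from it; (2) as 1 with NA-pairs removed from both sides;
(3) train without NA-pairs, test on exactly those NA-pairs; (4) train as
2, test on NA-pairs unique to the later release. Construction verifies
train/test disjointness by pair key.

Metrics are one-vs-rest per class from the K×K confusion matrix (rows
actual, columns predicted): Pre = TP/(TP+FP), Rec = TP/(TP+FN), and MCC
with the standard binary form; a degenerate MCC denominator (any zero
margin) maps to 0 with a warning. Printed-precision comparisons round
half-up to 2 decimals (percentages to whole numbers).

The two benchmark confusion matrices bundled in
`sseforest.benchmark_data` serve as a pinned regression input for this
metric pipeline. Note a documented inconsistency in the accompanying
published metric table: its strategy-1 Super-family MCC (0.69) and
strategy-2 Class MCC (0.81) cells do not derive from the matrices under
any rounding convention (they compute to 0.6585 and 0.8185); the
regression tests assert the matrix-derived values, and the acceptance
suite keeps the printed cells asserted as printed, where they fail.

## Decision rules for unassigned targets

Per template lineage (grouped by full family sccs):

1. each template contributes its argmax level and probability; NA argmax
   supports nothing;
2. the deepest argmax level across the lineage's templates is selected;
3. **promotion**: if at least 2 templates predict the shared level with
   p < 0.8 while assigning p > 0.2 to the next-deeper level, the
   suggestion moves to the deeper level. The shared-level probability is
   kept as the suggestion's evidence, since the deeper-level mass is a
   minority signal. The "multiple templates" requirement is a
   configurable minimum (default 2);
4. suggestions with p ≥ 0.5 are accepted; p ≥ 0.9 marks high confidence.
   Equality at 0.5/0.9 is tested after rounding p to 10 decimals, because
   averaged tree ratios produce values like 0.4999999999999999.

Multiple lineages may be suggested for one target (multi-domain chains);
suggestions are sorted by decreasing p and are invariant to template input
order. Probability bins for survey tables use the boundaries
p < 0.5 | p = 0.5 | 0.5 < p < 0.9 | p ≥ 0.9 with the same rounding guard.

Triangle (transitivity) violations are triples of domains where two edges
are predicted to share the same level L ∈ {CL, FO, SF, FA} but the third
edge's prediction differs; NA edges assert no shared level and never
anchor a triangle. Confident misclassifications (p ≥ 0.9) become
hierarchy-edit suggestions: a prediction deeper than the actual shared
level proposes merging the two actual nodes at the predicted level; a
shallower prediction proposes a new element at the actual level. "Deeper"
is ordered NA < CL < FO < SF < FA.

## Synthetic data generator

The generator exists so the whole pipeline is testable with no downloads.

* **Geometry**: Cα atoms on ideal curves — helix rise 1.5 Å/residue,
  radius 2.3 Å, twist 100°/residue; strand rise 3.3 Å/residue, straight.
  Centroids and axes are therefore analytically known. Two coil-linker
  residues separate consecutive SSEs.
* **Hierarchy**: a base layout of N SSEs (default N = 3; positions spaced
  ~12 Å, random orientations, lengths 4–10 for helices / 3–7 for strands,
  per-SSE accessibility means 20–80 Å²) is perturbed down the tree with
  strictly decreasing scales σ = (16, 4, 1, 0.25) Å at the class, fold,
  superfamily and family levels, and σ_fa/4 per domain within a family.
  Direction noise scales at 0.02×σ (radian-like), accessibility at 2×σ,
  integer lengths at 0.1×σ (frozen below the family level so that
  within-family length differences are exactly zero). The ×4 ratio
  between consecutive scales makes descriptor similarity a faithful proxy
  for shared depth, the premise of the method.
* **Sequences**: each family draws a random prototype; domains substitute
  each position with probability 0.5, putting within-family identity near
  0.25–0.30 — remote-homolog range — so the identity feature is
  informative and the 35% filter removes a minority of same-family pairs.
  Families have independent prototypes; cross-family identity is
  alignment noise.
* Default shape 2 classes × 2 folds × 2 superfamilies × 2 families with 3
  domains per family (48 domains, 1 128 pairs before filtering).

What the generator does **not** emulate: real packing constraints,
side-chain or hydrogen-bond physics, DSSP assignment noise, inserted or
missing residues, domains split across chains, and the heavy-tailed and
correlated class populations of real SCOP releases. Passing the recovery
benchmark therefore demonstrates that the pipeline implements its
contracts and that the learner recovers a hierarchy whose descriptor
dispersion behaves as assumed — not that real-SCOP accuracy is matched.

## Benchmark problem sizes

The recovery benchmark uses 5 domains per family (80 domains, 3 160 pairs
before filtering, ≈2 200 training / ≈940 held-out pairs after a stratified
70/30 split), chosen so that every pair class, including FA after identity
filtering, has at least 30 held-out pairs. The imbalance stress variant
down-samples FO and SF jointly to ≈2.5 % of the training rows and re-tests.
Both runs complete in a couple of seconds on one CPU.

## Known limitations

* The feature layout is a documented reconstruction: the closed-form M
  stated with the original descriptor scheme was not available, so the
  layout (raw values of both domains + RMS differences + identity) is
  versioned and nothing downstream depends on the absolute M.
* Sequence identity of the original benchmark pipeline is unspecified;
  the BLOSUM62 global-alignment definition here is pinned in one place.
* Targets are compared only against equal-N templates; unequal-N
  comparison (common-core search) is out of scope.
* DSSP is consumed as files; the package never recomputes hydrogen-bond
  assignments. The plain TSV annotation format written by `simulate` is
  for synthetic fixtures only and is clearly not DSSP.
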