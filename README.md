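# sseforest

Template-based SCOP structure classification of small protein domains with
a random forest over secondary-structure-element (SSE) descriptors.

Manual curation of the SCOP hierarchy (Class → Fold → Super-family →
Family) lags far behind structure deposition. `sseforest` is for
structural bioinformaticians who want a fast, probabilistic first pass: it
takes a *target* domain and *template* domains with known classification
(same number N of SSEs), and predicts the deepest level the pair shares —
CL, FO, SF, FA, or NA for none — together with a probability. The
per-pair predictions are then combined into classification proposals for
unassigned chains and for domains parked in SCOP's "Not a true class"
place-holders, and into merger / new-sublevel suggestions for the
hierarchy itself.

## Model

Each SSE is summarised by its Cα centroid, its first→last Cα axis, its
summed solvent accessibility, length, and a binary type (0 = α-helix).
A (target, template) pair becomes a vector of M = 2N(N−1) + 6N + 5
features: both domains' inter-SSE centroid distances and inter-axis angles
(matched by sequential SSE index), both domains' per-SSE
accessibility/length/type, four RMS differences over the structurally
equivalent entries, and the pair's sequence identity (global alignment;
pairs at ≥ 35 % identity are discarded).

A forest of T = 10 unpruned trees is bagged over training pairs; each node
picks the best information-gain split among m = ⌊log₂(M+1)⌋ randomly drawn
features. The predicted probability of level L is the mean over trees of
the leaf class ratio

  p(L) = (1/T) Σₜ  n_L(leafₜ) / n(leafₜ),

and the argmax level is reported. Proposals for unassigned targets accept
suggestions at p ≥ 0.5 (high confidence at p ≥ 0.9) and promote a lineage
to the next-deeper level when ≥ 2 of its templates give the shared level
p < 0.8 but the deeper level p > 0.2. Evaluation reports accuracy and
per-class precision, recall and Matthews correlation coefficient from the
actual × predicted confusion matrix.

See `docs/methods.md` for the full description, defaults and limitations.

## Worked example

A complete no-download run on the bundled synthetic hierarchy generator
(32 domains in a 2×2×2×2 hierarchy, two domains per family):

```
$ sseforest simulate --out-dir fixtures --seed 5 --domains 2
32 domains, 493 labelled pairs -> fixtures

$ sseforest train --features fixtures/pairs.tsv --trees 10 --seed 7 --out model.json
10 trees, m=5, oob accuracy 0.976

$ sseforest predict --model model.json --features fixtures/pairs.tsv --out pred.tsv
493 predictions -> pred.tsv

$ sseforest evaluate --pred pred.tsv --truth fixtures/pairs.tsv --out report.json
accuracy 0.9959 on 493 pairs
```

`simulate` wrote 493 labelled pairs (of the 496 possible pairs of 32
domains, 3 were removed by the 35 % identity filter). Training reports
m = 5 feature candidates per node (M = 35 for N = 3 SSEs) and an
out-of-bag accuracy of 0.976 — an internal estimate of generalisation.
The final line is resubstitution accuracy on the training pairs;
`report.json` holds the confusion matrix, per-class Pre/Rec/MCC and the
probability-bin table. For a proper held-out number, the library runs the
same pipeline with a stratified 70/30 pair split:

```python
>>> from sseforest import recovery_benchmark
>>> res = recovery_benchmark(seed=1)
>>> round(res["accuracy"], 4), round(res["per_class"]["FA"]["mcc"], 4)
(0.9989, 0.9862)
```

i.e. on 938 held-out pairs the pair-type accuracy is 99.89 % and the
Family-class MCC is 0.986. Classification proposals for unassigned targets
come from `sseforest classify-target` (or `sseforest.classify_target` in
Python), which turns per-template predictions into accepted / high-
confidence suggestions per lineage.

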