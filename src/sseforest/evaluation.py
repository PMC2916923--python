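"""Metrics, probability binning and the target-classification decision rules.

Accuracy, per-class precision/recall and the Matthews correlation
coefficient (MCC) are computed from a K×K confusion matrix (rows = actual,
columns = predicted) in a one-vs-rest fashion:

    Pre = TP / (TP + FP)
    Rec = TP / (TP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with a degenerate denominator (any zero margin) mapped to 0 with a warning.

The module also implements the decision rules used to propose SCOP
classifications for unassigned target domains from per-template forest
predictions: acceptance at probability p ≥ 0.5, high confidence at p ≥ 0.9,
promotion to the next-deeper level when multiple templates of one lineage
predict the shared level weakly (p < 0.8) while giving the deeper level
p > 0.2, triangle-transitivity violation detection, and
merger / new-sublevel suggestions from confidently (p ≥ 0.9) misclassified
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .forest import Prediction
from .scop_labels import DEEPER_LEVEL, LEVEL_DEPTH, Lineage

#: Probability-bin labels, in increasing order of confidence.
PROBABILITY_BINS: tuple[str, ...] = ("p<0.5", "p=0.5", "0.5<p<0.9", "p>=0.9")

#: Decimal places used to guard floating-point equality at bin boundaries
#: (averaged tree ratios produce values like 0.4999999999).
_P_DECIMALS = 10

ACCEPT_THRESHOLD = 0.5
HIGH_CONFIDENCE_THRESHOLD = 0.9
PROMOTION_SHARED_CAP = 0.8
PROMOTION_DEEPER_FLOOR = 0.2


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed-table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K×K confusion counts; rows are actual classes, columns predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    actual: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Tabulate actual × predicted label counts in the given class order."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(index), len(index)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"unknown label in ({a!r}, {p!r})")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(tuple(class_order), counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly predicted pairs: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class_counts(cm: ConfusionMatrix, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for one class."""
    if cls not in cm.labels:
        raise ValueError(f"unknown class: {cls!r}")
    i = cm.labels.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Binary Matthews correlation coefficient; 0 on degenerate margins."""
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("degenerate MCC margin; returning 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom2))


def precision(tp: int, fp: int) -> float:
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    return tp / (tp + fn) if tp + fn else 0.0


@dataclass
class MetricReport:
    """Overall accuracy plus per-class Pre/Rec/MCC and one-vs-rest counts."""

    accuracy: float
    per_class: dict[str, dict[str, float]]


def metric_report(cm: ConfusionMatrix, classes: Sequence[str] | None = None) -> MetricReport:
    """Compute the full metric block from a confusion matrix.

    ``classes`` restricts reporting (e.g. to the classes present in the
    test set); defaults to every class of the matrix.
    """
    out: dict[str, dict[str, float]] = {}
    for cls in classes if classes is not None else cm.labels:
        tp, fp, fn, tn = per_class_counts(cm, cls)
        out[cls] = {
            "precision": precision(tp, fp),
            "recall": recall(tp, fn),
            "mcc": mcc(tp, fp, fn, tn),
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }
    return MetricReport(accuracy=accuracy(cm), per_class=out)


@dataclass
class ProbabilityBins:
    """Per-predicted-level counts in the four probability bins."""

    table: dict[str, dict[str, int]] = field(default_factory=dict)

    def total(self, level: str) -> int:
        return sum(self.table.get(level, {}).values())


def _bin_of(p: float) -> str:
    if not 0.0 <= p <= 1.0 + 1e-12:
        raise ValueError(f"probability out of range: {p}")
    p = round(p, _P_DECIMALS)
    if p < 0.5:
        return "p<0.5"
    if p == 0.5:
        return "p=0.5"
    if p < 0.9:
        return "0.5<p<0.9"
    return "p>=0.9"


def bin_probabilities(predictions: Iterable[tuple[str, float]]) -> ProbabilityBins:
    """Bin (predicted level, p) records into the four probability bins.

    Bin boundaries: p < 0.5 | p = 0.5 | 0.5 < p < 0.9 | p ≥ 0.9, with
    equality tested after rounding p to 10 decimal places.
    """
    bins = ProbabilityBins()
    for level, p in predictions:
        row = bins.table.setdefault(level, {b: 0 for b in PROBABILITY_BINS})
        row[_bin_of(p)] += 1
    return bins


@dataclass(frozen=True)
class TemplateHit:
    """One (target, template) prediction with the template's lineage."""

    template_id: str
    lineage: Lineage
    prediction: Prediction


@dataclass(frozen=True)
class TargetSuggestion:
    """A proposed classification of a target at one lineage node."""

    target_id: str
    level: str  # CL | FO | SF | FA
    node: str  # lineage prefix at `level`
    sunid: int | None
    templates: tuple[str, ...]
    p: float
    tier: str  # "accepted" (p >= 0.5) | "high" (p >= 0.9)


def classify_target(
    target_id: str,
    template_predictions: Iterable[TemplateHit],
    accept_threshold: float = ACCEPT_THRESHOLD,
    high_threshold: float = HIGH_CONFIDENCE_THRESHOLD,
    promotion_shared_cap: float = PROMOTION_SHARED_CAP,
    promotion_deeper_floor: float = PROMOTION_DEEPER_FLOOR,
    min_promoting_templates: int = 2,
) -> list[TargetSuggestion]:
    """Propose classifications for an unassigned target from template hits.

    Per template lineage (grouped by full family sccs):

    1. every template contributes its argmax level and probability;
       templates whose argmax is NA support nothing;
    2. the deepest argmax level across the lineage's templates is selected;
    3. if at least ``min_promoting_templates`` templates predict that shared
       level with p below ``promotion_shared_cap`` while assigning more than
       ``promotion_deeper_floor`` to the next-deeper level, the suggestion
       is promoted to the deeper level (the shared-level probability is kept
       as the suggestion's evidence);
    4. suggestions with p ≥ ``accept_threshold`` are emitted, tier
       ``"high"`` at p ≥ ``high_threshold``, else ``"accepted"``.

    Multiple lineages may be suggested (multi-domain targets).  The output
    is sorted by decreasing p then node, and is invariant to input order.
    """
    groups: dict[str, list[TemplateHit]] = {}
    for hit in template_predictions:
        groups.setdefault(hit.lineage.fa, []).append(hit)

    suggestions: list[TargetSuggestion] = []
    for fa_node in sorted(groups):
        hits = sorted(groups[fa_node], key=lambda h: h.template_id)
        scored = [h for h in hits if h.prediction.label != "NA"]
        if not scored:
            continue
        level = max((h.prediction.label for h in scored),
                    key=lambda l: LEVEL_DEPTH[l])
        supporting = [h for h in scored if h.prediction.label == level]
        p = max(h.prediction.proba[level] for h in supporting)

        if level in DEEPER_LEVEL:
            deeper = DEEPER_LEVEL[level]
            weak = [
                h for h in supporting
                if h.prediction.proba[level] < promotion_shared_cap
                and h.prediction.proba[deeper] > promotion_deeper_floor
            ]
            if len(weak) >= min_promoting_templates:
                level = deeper
                supporting = weak
                p = max(h.prediction.proba[h.prediction.label] for h in weak)

        if round(p, _P_DECIMALS) < accept_threshold:
            continue
        lineage = supporting[0].lineage
        suggestions.append(
            TargetSuggestion(
                target_id=target_id,
                level=level,
                node=lineage.prefix(level),
                sunid=lineage.sunid,
                templates=tuple(h.template_id for h in supporting),
                p=p,
                tier="high" if round(p, _P_DECIMALS) >= high_threshold
                else "accepted",
            )
        )
    suggestions.sort(key=lambda s: (-s.p, s.node))
    return suggestions


def triangle_violations(
    predictions: Mapping[frozenset[str] | tuple[str, str], str],
) -> list[tuple[str, str, str]]:
    """Find triples breaking the triangle (transitivity) relationship.

    If pairs (i, j) and (j, k) are both predicted to share level L (one of
    CL/FO/SF/FA), pair (i, k) should be predicted to share L too; triples
    where it is not are returned as sorted (i, j, k) tuples.  NA edges
    assert no shared level and therefore never anchor a triangle.
    """
    edges: dict[frozenset[str], str] = {frozenset(k): v for k, v in predictions.items()}
    domains = sorted({d for key in edges for d in key})
    violations: list[tuple[str, str, str]] = []
    for i, j, k in combinations(domains, 3):
        trio = [frozenset((i, j)), frozenset((j, k)), frozenset((i, k))]
        if not all(e in edges for e in trio):
            continue
        labels = [edges[e] for e in trio]
        for a, b, c in ((0, 1, 2), (0, 2, 1), (1, 2, 0)):
            if labels[a] == labels[b] and labels[a] != "NA" and labels[c] != labels[a]:
                violations.append((i, j, k))
                break
    return violations


@dataclass(frozen=True)
class EvaluatedPair:
    """A test pair with its actual and predicted labels and probability."""

    sid_a: str
    sid_b: str
    lineage_a: Lineage
    lineage_b: Lineage
    actual: str
    predicted: str
    p: float


@dataclass(frozen=True)
class MergerSuggestion:
    """A proposed hierarchy edit derived from a confident misclassification."""

    kind: str  # "merge" | "new_sublevel"
    level: str
    nodes: tuple[str, ...]
    pair: tuple[str, str]
    p: float


def merger_suggestions(
    pairs: Iterable[EvaluatedPair],
    threshold: float = HIGH_CONFIDENCE_THRESHOLD,
) -> list[MergerSuggestion]:
    """Turn confidently misclassified pairs into hierarchy-edit suggestions.

    A pair misclassified with p ≥ 0.9 whose predicted level is *deeper*
    than its actual shared level suggests merging the two actual nodes at
    the predicted level; a prediction *shallower* than the actual level
    suggests a new element at the actual (deeper) level under the shared
    node.
    """
    out: list[MergerSuggestion] = []
    for pr in pairs:
        if pr.predicted == pr.actual or round(pr.p, _P_DECIMALS) < threshold:
            continue
        if LEVEL_DEPTH[pr.predicted] > LEVEL_DEPTH[pr.actual]:
            out.append(
                MergerSuggestion(
                    kind="merge",
                    level=pr.predicted,
                    nodes=(
                        pr.lineage_a.prefix(pr.predicted),
                        pr.lineage_b.prefix(pr.predicted),
                    ),
                    pair=(pr.sid_a, pr.sid_b),
                    p=pr.p,
                )
            )
        elif pr.actual != "NA":
            out.append(
                MergerSuggestion(
                    kind="new_sublevel",
                    level=pr.actual,
                    nodes=(pr.lineage_a.prefix(pr.actual),),
                    pair=(pr.sid_a, pr.sid_b),
                    p=pr.p,
                )
            )
    return out
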