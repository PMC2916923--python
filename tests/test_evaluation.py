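"""Confusion-matrix metrics, probability bins and the decision rules."""

from __future__ import annotations

import numpy as np
import pytest

from sseforest import evaluation as ev
from sseforest.benchmark_data import (
    STRATEGY1_CONFUSION,
    STRATEGY2_CONFUSION,
    STRATEGY_SET_SIZES,
)
from sseforest.forest import Prediction
from sseforest.scop_labels import parse_sccs

# ---------------------------------------------------------------------------
# confusion and accuracy


def test_confusion_single_hit():
    cm = ev.confusion(["CL"], ["CL"], ("CL", "FO"))
    assert cm.counts[0, 0] == 1
    assert cm.total == 1


def test_confusion_all_wrong_zero_diagonal():
    cm = ev.confusion(["CL", "FO"], ["FO", "CL"], ("CL", "FO"))
    assert np.trace(cm.counts) == 0


def test_confusion_rejects_unknown_label():
    with pytest.raises(ValueError, match="unknown label"):
        ev.confusion(["XX"], ["CL"], ("CL",))


def test_accuracy_identity_matrix():
    cm = ev.ConfusionMatrix(("A", "B"), np.eye(2, dtype=int) * 5)
    assert ev.accuracy(cm) == 1.0


def test_accuracy_empty_matrix_errors():
    cm = ev.ConfusionMatrix(("A",), np.zeros((1, 1), dtype=int))
    with pytest.raises(ValueError, match="empty"):
        ev.accuracy(cm)


# ---------------------------------------------------------------------------
# benchmark-matrix regression (pinned):
# metrics recomputed from the published inter-version confusion matrices


def test_benchmark_matrix_totals_match_published_test_sizes():
    assert STRATEGY1_CONFUSION.total == STRATEGY_SET_SIZES[1][1] == 6606
    assert STRATEGY2_CONFUSION.total == STRATEGY_SET_SIZES[2][1] == 4114


def test_benchmark_accuracies():
    assert ev.round_half_up(ev.accuracy(STRATEGY1_CONFUSION), 2) == 0.85
    assert ev.round_half_up(ev.accuracy(STRATEGY2_CONFUSION), 2) == 0.93


def test_strategy1_family_counts():
    assert ev.per_class_counts(STRATEGY1_CONFUSION, "FA") == (336, 74, 52, 6144)


def test_strategy1_superfamily_counts():
    tp, fp, _, _ = ev.per_class_counts(STRATEGY1_CONFUSION, "SF")
    assert (tp, fp) == (56, 14)


def test_single_class_matrix_has_no_errors():
    cm = ev.ConfusionMatrix(("A",), np.array([[9]]))
    assert ev.per_class_counts(cm, "A") == (9, 0, 0, 0)


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((336, 74, 52, 6144), 0.83),  # strategy-1 Family
        ((125, 20, 153, 6308), 0.61),  # strategy-1 Fold
    ],
)
def test_mcc_from_counts(counts, expected):
    assert ev.round_half_up(ev.mcc(*counts), 2) == expected


def test_mcc_perfect_predictor_is_one():
    assert ev.mcc(50, 0, 0, 50) == pytest.approx(1.0)


def test_mcc_degenerate_margin_is_zero_with_warning():
    with pytest.warns(UserWarning, match="degenerate"):
        assert ev.mcc(0, 0, 5, 5) == 0.0


def test_per_class_counts_consistency():
    """Rec·(TP+FN) = TP and TP+FP+FN+TN = total for every class."""
    for cm in (STRATEGY1_CONFUSION, STRATEGY2_CONFUSION):
        for cls in cm.labels:
            tp, fp, fn, tn = ev.per_class_counts(cm, cls)
            assert tp + fp + fn + tn == cm.total
            rec = ev.recall(tp, fn)
            assert rec * (tp + fn) == pytest.approx(tp)


# Pre/Rec/MCC derived from the published matrices, at 2 d.p. half-up.  The
# strategy-1 SF MCC and strategy-2 CL MCC derive to 0.66 and 0.82 here.
MATRIX_DERIVED_METRICS = {
    1: {
        "CL": (0.89, 0.84, 0.73),
        "FO": (0.86, 0.45, 0.61),
        "SF": (0.80, 0.55, 0.66),
        "FA": (0.82, 0.87, 0.83),
        "NA": (0.81, 0.91, 0.76),
    },
    2: {
        "CL": (0.94, 0.99, 0.82),
        "FO": (0.93, 0.41, 0.61),
        "SF": (0.75, 0.55, 0.63),
        "FA": (0.84, 0.85, 0.83),
    },
}


@pytest.mark.parametrize("strategy", [1, 2])
def test_metric_report_matches_matrix_derivation(strategy):
    cm = STRATEGY1_CONFUSION if strategy == 1 else STRATEGY2_CONFUSION
    report = ev.metric_report(cm)
    for cls, (pre, rec, mcc_val) in MATRIX_DERIVED_METRICS[strategy].items():
        got = report.per_class[cls]
        assert ev.round_half_up(got["precision"], 2) == pre
        assert ev.round_half_up(got["recall"], 2) == rec
        assert ev.round_half_up(got["mcc"], 2) == mcc_val


# ---------------------------------------------------------------------------
# probability bins


@pytest.mark.parametrize(
    "p, expected",
    [
        (0.49, "p<0.5"),
        (0.5, "p=0.5"),
        (1 / 3 + 1 / 6, "p=0.5"),  # 0.4999999999999999 rounds into the bin
        (0.51, "0.5<p<0.9"),
        (0.89, "0.5<p<0.9"),
        (0.9, "p>=0.9"),
        (1.0, "p>=0.9"),
    ],
)
def test_bin_boundaries(p, expected):
    bins = ev.bin_probabilities([("CL", p)])
    assert bins.table["CL"][expected] == 1
    assert bins.total("CL") == 1


def test_bin_totals_per_level():
    preds = [("CL", 0.3), ("CL", 0.5), ("CL", 0.95), ("FA", 0.6)]
    bins = ev.bin_probabilities(preds)
    assert bins.total("CL") == 3
    assert bins.total("FA") == 1


def test_bin_rejects_out_of_range():
    with pytest.raises(ValueError, match="out of range"):
        ev.bin_probabilities([("CL", 1.5)])


# ---------------------------------------------------------------------------
# target classification rules


def _hit(template_id, sccs, proba, sunid=None):
    label = max(proba, key=lambda c: (proba[c], -list(proba).index(c)))
    return ev.TemplateHit(
        template_id=template_id,
        lineage=parse_sccs(sccs, sunid),
        prediction=Prediction(proba=proba, label=label),
    )


def _proba(**kwargs):
    base = {"CL": 0.0, "FO": 0.0, "SF": 0.0, "FA": 0.0, "NA": 0.0}
    base.update(kwargs)
    rest = 1.0 - sum(base.values())
    base["NA"] += rest
    return base


def test_single_template_family_acceptance():
    hits = [_hit("t1", "a.7.6.1", _proba(FA=0.9, SF=0.05), sunid=46912)]
    out = ev.classify_target("q1", hits)
    assert len(out) == 1
    s = out[0]
    assert (s.level, s.node, s.sunid, s.tier) == ("FA", "a.7.6.1", 46912, "high")
    assert s.p == pytest.approx(0.9)


def test_promotion_to_deeper_level():
    """Two weak fold-level templates with deeper-level mass promote to SF."""
    hits = [
        _hit("t1", "a.7.6.1", _proba(FO=0.7, SF=0.25)),
        _hit("t2", "a.7.6.1", _proba(FO=0.7, SF=0.25)),
    ]
    out = ev.classify_target("q2", hits)
    assert len(out) == 1
    assert out[0].level == "SF"
    assert out[0].node == "a.7.6"
    assert set(out[0].templates) == {"t1", "t2"}


def test_single_weak_template_not_promoted():
    hits = [_hit("t1", "a.7.6.1", _proba(FO=0.7, SF=0.25))]
    out = ev.classify_target("q3", hits)
    assert out[0].level == "FO"


def test_strong_shared_level_not_promoted():
    hits = [
        _hit("t1", "a.7.6.1", _proba(FO=0.85, SF=0.1)),
        _hit("t2", "a.7.6.1", _proba(FO=0.85, SF=0.1)),
    ]
    out = ev.classify_target("q4", hits)
    assert out[0].level == "FO"


def test_deeper_template_prediction_wins_within_lineage():
    hits = [
        _hit("t1", "a.7.6.1", _proba(FO=0.8)),
        _hit("t2", "a.7.6.1", _proba(FA=0.6)),
    ]
    out = ev.classify_target("q5", hits)
    assert out[0].level == "FA"
    assert out[0].templates == ("t2",)


def test_multiple_lineages_reported():
    """Templates from two folds with accepted FO predictions -> two records."""
    hits = [
        _hit("t1", "a.4.1.1", _proba(FO=0.8)),
        _hit("t2", "a.118.1.1", _proba(FO=0.6)),
    ]
    out = ev.classify_target("q6", hits)
    assert [(s.level, s.node) for s in out] == [("FO", "a.4"), ("FO", "a.118")]


def test_below_acceptance_suppressed():
    hits = [_hit("t1", "a.7.6.1", _proba(FA=0.4))]
    assert ev.classify_target("q7", hits) == []


def test_classify_target_order_invariant():
    hits = [
        _hit("t1", "a.4.1.1", _proba(FO=0.8)),
        _hit("t2", "a.118.1.1", _proba(FO=0.6)),
        _hit("t3", "a.118.1.1", _proba(FA=0.55)),
    ]
    forward = ev.classify_target("q8", hits)
    backward = ev.classify_target("q8", list(reversed(hits)))
    assert forward == backward


# ---------------------------------------------------------------------------
# triangle equality


def test_triangle_no_violation():
    preds = {("a", "b"): "FO", ("b", "c"): "FO", ("a", "c"): "FO"}
    assert ev.triangle_violations(preds) == []


def test_triangle_violation_fo_fo_na():
    preds = {("a", "b"): "FO", ("b", "c"): "FO", ("a", "c"): "NA"}
    assert ev.triangle_violations(preds) == [("a", "b", "c")]


def test_triangle_incomplete_graph_empty():
    preds = {("a", "b"): "FO", ("b", "c"): "FO"}
    assert ev.triangle_violations(preds) == []


def test_triangle_na_edges_do_not_anchor():
    preds = {("a", "b"): "NA", ("b", "c"): "NA", ("a", "c"): "FO"}
    assert ev.triangle_violations(preds) == []


# ---------------------------------------------------------------------------
# merger / new-sublevel suggestions


def _evaluated(actual, predicted, p, sccs_a="i.1.1.1", sccs_b="a.7.6.1"):
    return ev.EvaluatedPair(
        "dA", "dB", parse_sccs(sccs_a), parse_sccs(sccs_b), actual, predicted, p
    )


def test_merger_from_confident_deeper_prediction():
    out = ev.merger_suggestions([_evaluated("NA", "FA", 0.9)])
    assert len(out) == 1
    assert out[0].kind == "merge"
    assert out[0].nodes == ("i.1.1.1", "a.7.6.1")


def test_merger_from_sf_pair_predicted_family():
    out = ev.merger_suggestions(
        [_evaluated("SF", "FA", 0.95, "a.7.6.1", "a.7.6.2")]
    )
    assert out[0].kind == "merge"
    assert out[0].level == "FA"
    assert out[0].nodes == ("a.7.6.1", "a.7.6.2")


def test_no_record_for_correct_or_uncertain_pairs():
    assert ev.merger_suggestions([_evaluated("FA", "FA", 0.99)]) == []
    assert ev.merger_suggestions([_evaluated("NA", "FA", 0.6)]) == []


def test_new_sublevel_from_shallow_prediction():
    out = ev.merger_suggestions(
        [_evaluated("FA", "SF", 0.92, "a.7.6.1", "a.7.6.1")]
    )
    assert out[0].kind == "new_sublevel"
    assert out[0].level == "FA"
    assert out[0].nodes == ("a.7.6.1",)
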