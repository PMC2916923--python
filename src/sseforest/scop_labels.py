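"""SCOP lineage parsing, pair typing and train/test strategy construction.

A SCOP concise classification string (sccs) such as ``a.7.6.1`` encodes the
four-level lineage class.fold.superfamily.family of a domain.  A pair of
domains is labelled by the deepest level the two lineages share: ``FA`` if
they are in the same family, else ``SF``, ``FO`` or ``CL``, and ``NA`` if
they share none of the four levels.

The module also encodes the four benchmark train/test strategies built from
two consecutive SCOP releases (here called the 1.69 and 1.73 pair sets):

========  ==============================  =====================================
strategy  training set                    test set
========  ==============================  =====================================
1         all 1.69 pairs                  1.73 pairs absent from 1.69
2         1.69 pairs without NA-pairs     unique 1.73 pairs without NA-pairs
3         1.69 pairs without NA-pairs     the NA-pairs of 1.69
4         1.69 pairs without NA-pairs     NA-pairs unique to 1.73
========  ==============================  =====================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Canonical pair-label alphabet, in the fixed order used for argmax tie-breaks.
PAIR_CLASSES: tuple[str, ...] = ("CL", "FO", "SF", "FA", "NA")

#: Depth of each pair label in the hierarchy.  NA (no shared level) is
#: shallower than CL; FA is the deepest level.
LEVEL_DEPTH: dict[str, int] = {"NA": 0, "CL": 1, "FO": 2, "SF": 3, "FA": 4}

#: The next-deeper structural level, used by the promotion rule of
#: :func:`sseforest.evaluation.classify_target`.
DEEPER_LEVEL: dict[str, str] = {"CL": "FO", "FO": "SF", "SF": "FA"}

#: The four "Not a true class" place-holder classes of SCOP (low-resolution
#: structures, peptides, designed proteins, coiled coils).
PLACEHOLDER_CLASSES: frozenset[str] = frozenset("hijk")

_SCCS_RE = re.compile(r"^([a-zA-Z])\.(\d+)\.(\d+)\.(\d+)$")


@dataclass(frozen=True)
class Lineage:
    """A parsed four-level SCOP lineage.

    Each level string is a prefix extension of the previous one, e.g. for
    sccs ``a.7.6.1``: cl=``a``, fo=``a.7``, sf=``a.7.6``, fa=``a.7.6.1``.
    """

    cl: str
    fo: str
    sf: str
    fa: str
    sunid: int | None = None

    @property
    def sccs(self) -> str:
        return self.fa

    def prefix(self, level: str) -> str:
        """The lineage node identifier at ``level`` (one of CL/FO/SF/FA)."""
        return {"CL": self.cl, "FO": self.fo, "SF": self.sf, "FA": self.fa}[level]


def parse_sccs(sccs: str, sunid: int | None = None) -> Lineage:
    """Parse an sccs string into a :class:`Lineage`.

    Raises :class:`ValueError` on anything other than
    ``<letter>.<int>.<int>.<int>``.
    """
    m = _SCCS_RE.match(sccs.strip())
    if m is None:
        raise ValueError(f"malformed sccs: {sccs!r}")
    cl, fo, sf, fa = m.groups()
    return Lineage(
        cl=cl,
        fo=f"{cl}.{fo}",
        sf=f"{cl}.{fo}.{sf}",
        fa=f"{cl}.{fo}.{sf}.{fa}",
        sunid=sunid,
    )


def pair_type(a: Lineage, b: Lineage) -> str:
    """The deepest SCOP level shared by two lineages: FA/SF/FO/CL, or NA."""
    if a.fa == b.fa:
        return "FA"
    if a.sf == b.sf:
        return "SF"
    if a.fo == b.fo:
        return "FO"
    if a.cl == b.cl:
        return "CL"
    return "NA"


def is_placeholder_class(
    lineage: Lineage, placeholder_set: Iterable[str] = PLACEHOLDER_CLASSES
) -> bool:
    """Whether the lineage's class is one of SCOP's "Not a true class" letters."""
    return lineage.cl in set(placeholder_set)


@dataclass(frozen=True)
class LabelledPair:
    """An unordered labelled domain pair; sids identify the pair across releases."""

    sid_a: str
    sid_b: str
    sccs_a: str
    sccs_b: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in PAIR_CLASSES:
            raise ValueError(f"unknown pair label: {self.label!r}")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.sid_a, self.sid_b))


def label_pair(sid_a: str, sccs_a: str, sid_b: str, sccs_b: str) -> LabelledPair:
    """Build a :class:`LabelledPair` from two (sid, sccs) domain records."""
    lab = pair_type(parse_sccs(sccs_a), parse_sccs(sccs_b))
    return LabelledPair(sid_a, sid_b, sccs_a, sccs_b, lab)


@dataclass(frozen=True)
class StrategySpec:
    """One row of the four-strategy benchmark design."""

    id: int
    drop_na_from_train: bool
    drop_na_from_test: bool
    test_unique_only: bool
    test_na_only: bool = False
    test_from_train_release: bool = False


STRATEGIES: dict[int, StrategySpec] = {
    1: StrategySpec(1, drop_na_from_train=False, drop_na_from_test=False,
                    test_unique_only=True),
    2: StrategySpec(2, drop_na_from_train=True, drop_na_from_test=True,
                    test_unique_only=True),
    3: StrategySpec(3, drop_na_from_train=True, drop_na_from_test=False,
                    test_unique_only=False, test_na_only=True,
                    test_from_train_release=True),
    4: StrategySpec(4, drop_na_from_train=True, drop_na_from_test=False,
                    test_unique_only=True, test_na_only=True),
}


def build_strategy(
    spec: StrategySpec | int,
    ds169: Sequence[LabelledPair],
    ds173: Sequence[LabelledPair],
) -> tuple[list[LabelledPair], list[LabelledPair]]:
    """Build the (train, test) pair sets for one benchmark strategy.

    ``ds169`` is the earlier-release pair set used for training, ``ds173``
    the later-release set.  Pair identity across releases is the unordered
    sid pair.  Train and test are guaranteed disjoint by pair key.
    """
    if isinstance(spec, int):
        spec = STRATEGIES[spec]

    keys169 = {p.key for p in ds169}
    train = [p for p in ds169 if not (spec.drop_na_from_train and p.label == "NA")]

    if spec.test_from_train_release:
        # strategy 3: the NA-pairs removed from the training release
        test = [p for p in ds169 if p.label == "NA"]
    else:
        test = list(ds173)
        if spec.test_unique_only:
            test = [p for p in test if p.key not in keys169]
        if spec.drop_na_from_test:
            test = [p for p in test if p.label != "NA"]
        if spec.test_na_only:
            test = [p for p in test if p.label == "NA"]

    train_keys = {p.key for p in train}
    overlap = [p for p in test if p.key in train_keys]
    if overlap:
        raise RuntimeError(
            f"strategy {spec.id}: {len(overlap)} pairs appear in both train and test"
        )
    return train, test
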