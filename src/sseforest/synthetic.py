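"""Synthetic fixtures: ideal SSE geometries and labelled pair datasets drawn
from a four-level hierarchy.

``make_sse`` places Cα atoms on an ideal parameterised curve — a helix of
given rise, radius and twist per residue, or a straight strand — so the
centroid and the first→last axis of every generated SSE are analytically
known.  ``make_hierarchy`` emulates a SCOP-like population: each class
carries a prototype layout of N SSEs (positions, orientations, lengths,
accessibilities); fold, superfamily and family prototypes perturb it with
strictly decreasing noise scales, and individual domains add a final small
within-family perturbation.  Deeper shared levels therefore imply smaller
descriptor differences — the premise the classifier exploits.  Sequences
are conserved at the family level with a per-position substitution
probability chosen so that within-family identity sits in the
remote-homolog range (~0.25–0.30) and the 35% identity filter is
exercised.

``recovery_benchmark`` runs the full pipeline (generate → featurize →
filter → train → held-out evaluation) at desk scale and reports accuracy
and per-class MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from . import evaluation
from .descriptors import describe_domain, pair_feature_vector, sequence_identity
from .forest import TrainingSet, predict_batch, train_forest
from .scop_labels import PAIR_CLASSES, label_pair
from .structure_io import (
    IDENTITY_CUTOFF,
    MIN_HELIX_LEN,
    MIN_STRAND_LEN,
    SSE,
    AnnotatedDomain,
    Residue,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ideal geometry defaults per SSE kind: rise Å/residue, radius Å,
#: twist degrees/residue.
KIND_DEFAULTS = {
    "helix": {"rise": 1.5, "radius": 2.3, "twist": 100.0},
    "strand": {"rise": 3.3, "radius": 0.0, "twist": 0.0},
}


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of one ideal SSE curve."""

    kind: str
    n_res: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rise: float | None = None
    radius: float | None = None
    twist: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KIND_DEFAULTS:
            raise ValueError(f"unknown SSE kind: {self.kind!r}")
        minimum = MIN_HELIX_LEN if self.kind == "helix" else MIN_STRAND_LEN
        if self.n_res < minimum:
            raise ValueError(f"{self.kind} needs >= {minimum} residues")

    def resolved(self) -> tuple[float, float, float]:
        d = KIND_DEFAULTS[self.kind]
        return (
            d["rise"] if self.rise is None else self.rise,
            d["radius"] if self.radius is None else self.radius,
            d["twist"] if self.twist is None else self.twist,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("zero direction vector")
    return v / norm


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal pair perpendicular to ``direction``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(direction, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(direction, ref))
    v = np.cross(direction, u)
    return u, v


def sse_coordinates(spec: GeometrySpec) -> np.ndarray:
    """Cα coordinates (n_res, 3) of the ideal curve."""
    rise, radius, twist = spec.resolved()
    direction = _unit(np.asarray(spec.direction, dtype=float))
    origin = np.asarray(spec.origin, dtype=float)
    u, v = _frame(direction)
    k = np.arange(spec.n_res)
    theta = np.radians(twist) * k
    coords = (
        origin[None, :]
        + np.outer(k * rise, direction)
        + radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    )
    return coords


def make_sse(
    spec: GeometrySpec,
    start_index: int = 1,
    accessibility: float = 0.0,
    sequence: str | None = None,
) -> SSE:
    """Build an :class:`SSE` whose Cα trace follows the ideal curve."""
    coords = sse_coordinates(spec)
    ss_code = "H" if spec.kind == "helix" else "E"
    residues = [
        Residue(
            index=start_index + i,
            ca=coords[i],
            ss_code=ss_code,
            accessibility=accessibility,
            aa=sequence[i] if sequence else "A",
        )
        for i in range(spec.n_res)
    ]
    return SSE(spec.kind, start_index, start_index + spec.n_res - 1, residues)


def make_domain(
    specs: list[GeometrySpec],
    domain_id: str = "synthetic",
    accessibilities: list[float] | None = None,
    sequence: str | None = None,
    linker: int = 2,
) -> AnnotatedDomain:
    """Assemble a domain from SSE specs, with coil linkers in between.

    ``accessibilities`` gives the per-residue accessibility of each SSE
    (constant within an SSE).  ``sequence`` covers SSE and linker residues
    alike; when omitted a poly-alanine sequence is used.  ``linker`` coil
    residues (with interpolated Cα) separate consecutive SSEs so that
    segmentation recovers exactly ``len(specs)`` SSEs.
    """
    if len(specs) < 2:
        raise ValueError("a domain needs at least 2 SSEs")
    if accessibilities is not None and len(accessibilities) != len(specs):
        raise ValueError("one accessibility per SSE required")

    total = sum(s.n_res for s in specs) + linker * (len(specs) - 1)
    if sequence is None:
        sequence = "A" * total
    if len(sequence) != total:
        raise ValueError(f"sequence length {len(sequence)} != residue count {total}")

    residues: list[Residue] = []
    pos = 0
    for si, spec in enumerate(specs):
        acc = accessibilities[si] if accessibilities is not None else 0.0
        sse = make_sse(
            spec,
            start_index=len(residues) + 1,
            accessibility=max(0.0, acc),
            sequence=sequence[pos:pos + spec.n_res],
        )
        residues.extend(sse.residues)
        pos += spec.n_res
        if si + 1 < len(specs):
            here = sse.residues[-1].ca
            there = sse_coordinates(specs[si + 1])[0]
            for li in range(linker):
                t = (li + 1) / (linker + 1)
                residues.append(
                    Residue(
                        index=len(residues) + 1,
                        ca=here + t * (there - here),
                        ss_code="-",
                        accessibility=0.0,
                        aa=sequence[pos],
                    )
                )
                pos += 1
    domain = AnnotatedDomain.from_residues(domain_id, residues)
    if domain.n_sses != len(specs):
        raise RuntimeError("segmentation did not recover the generated SSEs")
    return domain


@dataclass(frozen=True)
class HierarchySpec:
    """Shape and dispersion of a synthetic four-level hierarchy.

    ``sigmas`` are the Å-scale perturbations added to the SSE layout at the
    class, fold, superfamily and family prototype levels; they must be
    positive and strictly decreasing so that deeper shared levels mean
    higher descriptor similarity.  ``domain_sigma`` (default σ_fa / 4) is
    the final within-family perturbation of each emitted domain.
    """

    n_classes: int = 2
    folds_per_class: int = 2
    sf_per_fold: int = 2
    fam_per_sf: int = 2
    domains_per_family: int = 3
    n_sses: int = 3
    sigmas: tuple[float, float, float, float] = (16.0, 4.0, 1.0, 0.25)
    domain_sigma: float | None = None
    direction_scale: float = 0.02
    accessibility_scale: float = 2.0
    length_scale: float = 0.1
    seq_mutation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_classes, self.folds_per_class, self.sf_per_fold,
                  self.fam_per_sf, self.domains_per_family)
        if any(c < 1 for c in counts):
            raise ValueError("all hierarchy counts must be >= 1")
        s = self.sigmas
        if any(x <= 0 for x in s) or not (s[0] > s[1] > s[2] > s[3]):
            raise ValueError("sigmas must be positive and strictly decreasing")

    @property
    def within_family_sigma(self) -> float:
        return self.sigmas[3] / 4 if self.domain_sigma is None else self.domain_sigma

    @property
    def n_domains(self) -> int:
        return (self.n_classes * self.folds_per_class * self.sf_per_fold
                * self.fam_per_sf * self.domains_per_family)


@dataclass(frozen=True)
class SyntheticDomain:
    """A generated domain with its synthetic sid and sccs lineage."""

    sid: str
    sccs: str
    domain: AnnotatedDomain


@dataclass
class _Layout:
    kinds: list[str]
    origins: np.ndarray  # (N, 3)
    directions: np.ndarray  # (N, 3) unit rows
    lengths: np.ndarray  # (N,) int
    accessibilities: np.ndarray  # (N,)


def _base_layout(spec: HierarchySpec, rng: np.random.Generator) -> _Layout:
    n = spec.n_sses
    kinds = ["helix" if rng.random() < 0.5 else "strand" for _ in range(n)]
    origins = np.column_stack(
        [12.0 * np.arange(n), np.zeros(n), np.zeros(n)]
    ) + rng.normal(0, 2.0, size=(n, 3))
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    lengths = np.array(
        [rng.integers(MIN_HELIX_LEN, 11) if k == "helix"
         else rng.integers(MIN_STRAND_LEN, 8) for k in kinds]
    )
    accessibilities = rng.uniform(20.0, 80.0, size=n)
    return _Layout(kinds, origins, directions, lengths, accessibilities)


def _perturb(
    layout: _Layout,
    sigma: float,
    spec: HierarchySpec,
    rng: np.random.Generator,
    perturb_lengths: bool = True,
) -> _Layout:
    n = spec.n_sses
    directions = layout.directions + rng.normal(
        0, sigma * spec.direction_scale, size=(n, 3)
    )
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    lengths = layout.lengths.copy()
    if perturb_lengths:
        lengths = lengths + np.rint(
            rng.normal(0, sigma * spec.length_scale, size=n)
        ).astype(int)
        minima = np.array(
            [MIN_HELIX_LEN if k == "helix" else MIN_STRAND_LEN for k in layout.kinds]
        )
        lengths = np.maximum(lengths, minima)
    return _Layout(
        kinds=list(layout.kinds),
        origins=layout.origins + rng.normal(0, sigma, size=(n, 3)),
        directions=directions,
        lengths=lengths,
        accessibilities=np.maximum(
            1.0,
            layout.accessibilities
            + rng.normal(0, sigma * spec.accessibility_scale, size=n),
        ),
    )


def _mutate(sequence: str, p: float, rng: np.random.Generator) -> str:
    out = []
    for aa in sequence:
        if rng.random() < p:
            out.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        else:
            out.append(aa)
    return "".join(out)


def make_hierarchy(spec: HierarchySpec) -> list[SyntheticDomain]:
    """Generate the labelled synthetic domain population.

    Deterministic for a given :class:`HierarchySpec` (including its seed).
    sccs strings are synthetic (``a.1.2.1``-style) but parse and label
    exactly like real ones.
    """
    rng = np.random.default_rng(spec.seed)
    linker = 2
    population: list[SyntheticDomain] = []
    counter = 0
    for ci in range(spec.n_classes):
        letter = chr(ord("a") + ci)
        class_proto = _perturb(_base_layout(spec, rng), spec.sigmas[0], spec, rng)
        for fo in range(1, spec.folds_per_class + 1):
            fold_proto = _perturb(class_proto, spec.sigmas[1], spec, rng)
            for sf in range(1, spec.sf_per_fold + 1):
                sf_proto = _perturb(fold_proto, spec.sigmas[2], spec, rng)
                for fa in range(1, spec.fam_per_sf + 1):
                    fam_proto = _perturb(sf_proto, spec.sigmas[3], spec, rng)
                    total = int(fam_proto.lengths.sum()) + linker * (spec.n_sses - 1)
                    fam_seq = "".join(
                        AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                        for _ in range(total)
                    )
                    sccs = f"{letter}.{fo}.{sf}.{fa}"
                    for _ in range(spec.domains_per_family):
                        dom_layout = _perturb(
                            fam_proto, spec.within_family_sigma, spec, rng,
                            perturb_lengths=False,
                        )
                        counter += 1
                        sid = f"dsyn{counter:04d}"
                        specs = [
                            GeometrySpec(
                                kind=dom_layout.kinds[i],
                                n_res=int(dom_layout.lengths[i]),
                                origin=tuple(dom_layout.origins[i]),
                                direction=tuple(dom_layout.directions[i]),
                            )
                            for i in range(spec.n_sses)
                        ]
                        domain = make_domain(
                            specs,
                            domain_id=sid,
                            accessibilities=list(dom_layout.accessibilities),
                            sequence=_mutate(fam_seq, spec.seq_mutation, rng),
                            linker=linker,
                        )
                        population.append(SyntheticDomain(sid, sccs, domain))
    return population


def make_pair_dataset(
    population: list[SyntheticDomain],
    identity_cutoff: float = IDENTITY_CUTOFF,
    class_set: tuple[str, ...] = PAIR_CLASSES,
) -> TrainingSet:
    """Featurize and label all unordered domain pairs below the identity cutoff."""
    if not population:
        raise ValueError("empty population")
    described = {d.sid: describe_domain(d.domain) for d in population}
    rows: list[np.ndarray] = []
    labels: list[str] = []
    keys: list[tuple[str, str]] = []
    for a, b in combinations(sorted(population, key=lambda d: d.sid), 2):
        ident = sequence_identity(a.domain.sequence, b.domain.sequence)
        if ident >= identity_cutoff:
            continue
        fv = pair_feature_vector(described[a.sid], described[b.sid], ident)
        rows.append(fv.values)
        labels.append(label_pair(a.sid, a.sccs, b.sid, b.sccs).label)
        keys.append((a.sid, b.sid))
    if not rows:
        return TrainingSet(np.empty((0, 0)), [], class_set, [])
    return TrainingSet(np.vstack(rows), labels, class_set, keys)


def stratified_split(
    data: TrainingSet, test_fraction: float, seed: int
) -> tuple[TrainingSet, TrainingSet]:
    """Per-class shuffled split into (train, test) subsets."""
    rng = np.random.default_rng(seed)
    labels = np.array(data.labels)
    test_idx: list[int] = []
    for cls in data.class_set:
        rows = np.flatnonzero(labels == cls)
        rng.shuffle(rows)
        n_test = int(round(test_fraction * len(rows)))
        test_idx.extend(rows[:n_test].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(labels)) if i not in test_set]
    return data.subset(train_idx), data.subset(sorted(test_idx))


def _subsample_minority(
    train: TrainingSet,
    minority: tuple[str, ...],
    target_fraction: float,
    seed: int,
) -> TrainingSet:
    """Down-sample the minority classes to ~``target_fraction`` of training."""
    rng = np.random.default_rng(seed)
    labels = np.array(train.labels)
    minority_rows = np.flatnonzero(np.isin(labels, minority))
    other_rows = np.flatnonzero(~np.isin(labels, minority))
    keep = max(
        len(minority),
        int(round(target_fraction / (1 - target_fraction) * len(other_rows))),
    )
    keep = min(keep, len(minority_rows))
    rng.shuffle(minority_rows)
    kept = np.concatenate([other_rows, minority_rows[:keep]])
    return train.subset(sorted(kept.tolist()))


def recovery_benchmark(
    seed: int = 0,
    hierarchy: HierarchySpec | None = None,
    test_fraction: float = 0.3,
    n_trees: int = 10,
    minority_fraction: float | None = None,
) -> dict:
    """End-to-end parameter recovery on the synthetic hierarchy.

    Generates the population, featurizes and identity-filters all pairs,
    splits pairs into train/held-out sets, trains the forest and evaluates
    on the held-out pairs.  ``minority_fraction`` optionally down-samples
    FO- and SF-pairs in training (imbalance stress).  Returns accuracy,
    per-class metrics and the class counts of the test set.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    if hierarchy is None:
        hierarchy = HierarchySpec(domains_per_family=5, seed=int(sub[0]))
    population = make_hierarchy(hierarchy)
    dataset = make_pair_dataset(population)
    train, test = stratified_split(dataset, test_fraction, int(sub[1]))
    if minority_fraction is not None:
        train = _subsample_minority(train, ("FO", "SF"), minority_fraction,
                                    int(sub[2]))
    model = train_forest(train, n_trees=n_trees, seed=int(sub[3]))
    predictions = predict_batch(model, test.features)
    cm = evaluation.confusion(
        test.labels, [p.label for p in predictions], dataset.class_set
    )
    report = evaluation.metric_report(cm)
    test_counts = {c: test.labels.count(c) for c in dataset.class_set}
    return {
        "n_domains": len(population),
        "n_pairs": len(dataset.labels),
        "n_train": len(train.labels),
        "n_test": len(test.labels),
        "test_counts": test_counts,
        "accuracy": report.accuracy,
        "per_class": report.per_class,
        "confusion": cm,
        "oob_accuracy": model.oob_accuracy,
    }
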