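"""Per-SSE and per-SSE-pair structural descriptors and the pair feature vector.

Each SSE is reduced to its geometric centroid (unweighted mean of Cα
positions), its axis (unit vector from the first to the last Cα), its total
solvent accessibility, its residue length and a binary type (0 for an
α-helix, 1 otherwise).  For every pair of SSEs within a domain, the
centroid-centroid distance (Å) and the inter-axis angle (degrees, folded to
[0, 180]) are computed.

Two domains with the same number N of SSEs are compared through a flat
feature vector (layout version "v1"):

* for every SSE pair i<j (in index order): distance of domain A, distance of
  domain B, angle of A, angle of B;
* for every SSE index i: accessibility of A and B, length of A and B,
  type of A and B;
* the four root-mean-square differences over structurally equivalent
  entries — distances, angles, accessibilities, lengths;
* the sequence identity of the two domains.

giving M = 2·N·(N−1) + 6·N + 5 features (35 for N = 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .structure_io import SSE, AnnotatedDomain

LAYOUT_VERSION = "v1"


@dataclass(frozen=True)
class SSEDescriptor:
    """Geometric summary of one SSE."""

    centroid: np.ndarray
    axis: np.ndarray
    accessibility: float
    length: int
    sstype: int  # 0 = alpha-helix, 1 = otherwise


@dataclass(frozen=True)
class DomainDescriptorSet:
    """All per-SSE and pairwise descriptors of one domain."""

    per_sse: tuple[SSEDescriptor, ...]
    pair_distance: np.ndarray  # (N, N) symmetric, Å
    pair_angle: np.ndarray  # (N, N) symmetric, degrees

    @property
    def n_sses(self) -> int:
        return len(self.per_sse)


@dataclass(frozen=True)
class PairFeatureVector:
    """The flat numeric representation of a (target, template) domain pair."""

    values: np.ndarray
    names: tuple[str, ...]
    identity: float
    layout_version: str = LAYOUT_VERSION

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


def sse_geometry(sse: SSE, accessibility_mode: str = "sum") -> SSEDescriptor:
    """Compute the descriptor of one SSE from its Cα trace.

    The centroid is the unweighted mean of the Cα positions; the axis is the
    normalised vector from the first to the last Cα (degenerate if they
    coincide).  Accessibility is summed over residues by default
    (``accessibility_mode="mean"`` averages instead).
    """
    coords = np.array([r.ca for r in sse.residues], dtype=float)
    if len(coords) < 3:
        raise ValueError("SSE needs at least 3 C-alpha coordinates")
    centroid = coords.mean(axis=0)
    delta = coords[-1] - coords[0]
    norm = np.linalg.norm(delta)
    if norm < 1e-12:
        raise ValueError("degenerate axis: first and last C-alpha coincide")
    acc = float(sum(r.accessibility for r in sse.residues))
    if accessibility_mode == "mean":
        acc /= len(sse.residues)
    elif accessibility_mode != "sum":
        raise ValueError(f"unknown accessibility_mode: {accessibility_mode!r}")
    return SSEDescriptor(
        centroid=centroid,
        axis=delta / norm,
        accessibility=acc,
        length=sse.length,
        sstype=0 if sse.kind == "helix" else 1,
    )


def pair_distance(a: SSEDescriptor, b: SSEDescriptor) -> float:
    """Euclidean distance between two SSE centroids, Å."""
    return float(np.linalg.norm(a.centroid - b.centroid))


def pair_angle(a: SSEDescriptor, b: SSEDescriptor) -> float:
    """Angle between two SSE axes in degrees, in [0, 180]."""
    dot = float(np.clip(np.dot(a.axis, b.axis), -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def describe_domain(
    domain: AnnotatedDomain, accessibility_mode: str = "sum"
) -> DomainDescriptorSet:
    """Compute the full descriptor set of a domain."""
    per_sse = tuple(sse_geometry(s, accessibility_mode) for s in domain.sses)
    n = len(per_sse)
    dist = np.zeros((n, n))
    ang = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pair_distance(per_sse[i], per_sse[j])
            ang[i, j] = ang[j, i] = pair_angle(per_sse[i], per_sse[j])
    return DomainDescriptorSet(per_sse, dist, ang)


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity of two amino-acid sequences.

    BLOSUM62 scoring with gap open −11 / extend −1; identity is the number
    of identical aligned positions divided by the alignment length
    (including gap columns).  Returns a fraction in [0, 1].
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    alignment = _aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length


def feature_count(n_sses: int) -> int:
    """Number of features M for a pair of domains each with ``n_sses`` SSEs."""
    if n_sses < 2:
        raise ValueError("a domain pair needs at least 2 SSEs per domain")
    n = n_sses
    return 2 * n * (n - 1) + 6 * n + 5


def feature_names(n_sses: int) -> tuple[str, ...]:
    """Ordered slot names of the v1 feature layout for ``n_sses`` SSEs."""
    names: list[str] = []
    for i in range(n_sses):
        for j in range(i + 1, n_sses):
            names += [
                f"dist_{i+1}{j+1}_a", f"dist_{i+1}{j+1}_b",
                f"angle_{i+1}{j+1}_a", f"angle_{i+1}{j+1}_b",
            ]
    for i in range(n_sses):
        names += [
            f"acc_{i+1}_a", f"acc_{i+1}_b",
            f"len_{i+1}_a", f"len_{i+1}_b",
            f"sstype_{i+1}_a", f"sstype_{i+1}_b",
        ]
    names += ["rmsd_distance", "rmsd_angle", "rmsd_accessibility", "rmsd_length",
              "identity"]
    return tuple(names)


def _upper(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]


def _rms(delta: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(delta))))


def pair_feature_vector(
    dom_a: DomainDescriptorSet,
    dom_b: DomainDescriptorSet,
    identity: float,
) -> PairFeatureVector:
    """Assemble the v1 feature vector for a (target, template) domain pair.

    The two domains must have the same number of SSEs; structurally
    equivalent SSEs and SSE pairs are matched by sequential (N→C) index.
    """
    if dom_a.n_sses != dom_b.n_sses:
        raise ValueError(
            f"SSE count mismatch: {dom_a.n_sses} vs {dom_b.n_sses}"
        )
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    n = dom_a.n_sses

    values: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            values += [
                dom_a.pair_distance[i, j], dom_b.pair_distance[i, j],
                dom_a.pair_angle[i, j], dom_b.pair_angle[i, j],
            ]
    for i in range(n):
        a, b = dom_a.per_sse[i], dom_b.per_sse[i]
        values += [a.accessibility, b.accessibility,
                   float(a.length), float(b.length),
                   float(a.sstype), float(b.sstype)]

    acc_a = np.array([s.accessibility for s in dom_a.per_sse])
    acc_b = np.array([s.accessibility for s in dom_b.per_sse])
    len_a = np.array([s.length for s in dom_a.per_sse], dtype=float)
    len_b = np.array([s.length for s in dom_b.per_sse], dtype=float)
    values += [
        _rms(_upper(dom_a.pair_distance) - _upper(dom_b.pair_distance)),
        _rms(_upper(dom_a.pair_angle) - _upper(dom_b.pair_angle)),
        _rms(acc_a - acc_b),
        _rms(len_a - len_b),
        identity,
    ]
    return PairFeatureVector(
        values=np.array(values, dtype=float),
        names=feature_names(n),
        identity=identity,
    )


def domain_pair_features(
    domain_a: AnnotatedDomain, domain_b: AnnotatedDomain
) -> PairFeatureVector:
    """Convenience: descriptors + sequence identity + feature vector."""
    ident = sequence_identity(domain_a.sequence, domain_b.sequence)
    return pair_feature_vector(describe_domain(domain_a),
                               describe_domain(domain_b), ident)
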