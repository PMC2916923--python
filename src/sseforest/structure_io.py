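"""Readers for coordinates, secondary-structure annotations and SCOP
classification files, plus SSE segmentation and the identity filter.

Coordinates are consumed from PDB files (Cα atoms only are required),
per-residue secondary structure and solvent accessibility from DSSP output
files, and domain classifications from ASTRAL ``dir.cla``-style text.  A
domain is segmented into its secondary structure elements (SSEs) by the
run-length rules: a helix needs at least four consecutive helix residues,
a strand at least three consecutive strand residues; everything else is
coil and never forms an SSE.
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, TypeVar

import gemmi
import numpy as np

#: DSSP codes treated as helix by default. {"H", "G", "I"} may be passed to
#: also count 3-10 and pi helices toward the four-residue helix rule.
DEFAULT_HELIX_CODES: frozenset[str] = frozenset({"H"})
STRAND_CODES: frozenset[str] = frozenset({"E"})
MIN_HELIX_LEN = 4
MIN_STRAND_LEN = 3

#: Default sequence-identity cutoff: pairs with identity strictly below 35%
#: are retained.
IDENTITY_CUTOFF = 0.35


@dataclass
class Residue:
    """One residue with its Cα position and per-residue annotations.

    ``index`` is the 1-based ordinal within the chain/domain; ``resnum`` and
    ``icode`` keep the author numbering for matching DSSP rows.
    """

    index: int
    ca: np.ndarray
    ss_code: str = "-"
    accessibility: float = 0.0
    aa: str = "X"
    resnum: int | None = None
    icode: str = ""

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (3,) or not np.all(np.isfinite(self.ca)):
            raise ValueError("ca must be a finite 3-vector")
        if self.accessibility < 0:
            raise ValueError("accessibility must be >= 0")


@dataclass
class SSE:
    """A contiguous helix or strand segment.

    ``start``/``end`` are inclusive 1-based residue ordinals; ``residues``
    holds the constituent residues in N→C order.
    """

    kind: str  # "helix" | "strand"
    start: int
    end: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"unknown SSE kind: {self.kind!r}")
        if self.end < self.start:
            raise ValueError("SSE end before start")
        minimum = MIN_HELIX_LEN if self.kind == "helix" else MIN_STRAND_LEN
        if self.length < minimum:
            raise ValueError(f"{self.kind} shorter than {minimum} residues")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedDomain:
    """A domain: its sequence and ordered, non-overlapping SSEs.

    ``residues`` optionally keeps the full residue list (including coil),
    so coordinate files can be written back without losing linkers.
    """

    id: str
    sequence: str
    sses: list[SSE]
    residues: list[Residue] | None = None

    def __post_init__(self) -> None:
        starts = [s.start for s in self.sses]
        if starts != sorted(starts):
            raise ValueError("SSEs must be ordered N->C")
        for prev, nxt in zip(self.sses, self.sses[1:]):
            if nxt.start <= prev.end:
                raise ValueError("overlapping SSEs")

    @property
    def n_sses(self) -> int:
        return len(self.sses)

    @classmethod
    def from_residues(
        cls,
        domain_id: str,
        residues: Sequence[Residue],
        helix_codes: frozenset[str] = DEFAULT_HELIX_CODES,
    ) -> "AnnotatedDomain":
        """Build a domain from annotated residues, segmenting its SSEs."""
        seq = "".join(r.aa for r in residues)
        return cls(domain_id, seq, segment_sses(residues, helix_codes=helix_codes),
                   residues=list(residues))


@dataclass(frozen=True)
class ClaRecord:
    """One line of an ASTRAL dir.cla-style classification file."""

    sid: str
    pdb: str
    region: str
    sccs: str
    sunid: int


def read_pdb_chain(path: str | Path, chain: str, model: int = 1) -> list[Residue]:
    """Read one chain's Cα trace from a PDB file.

    Returns one :class:`Residue` per residue that has a Cα atom, in file
    order.  Alternate locations are resolved to the highest-occupancy Cα
    (first encountered on ties); residues without a Cα are dropped.
    """
    structure = gemmi.read_structure(str(path))
    if not 1 <= model <= len(structure):
        raise ValueError(f"model {model} not present in {path}")
    mdl = structure[model - 1]
    target = None
    for ch in mdl:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"chain not found: {chain!r}")

    residues: list[Residue] = []
    for res in target:
        best = None
        for atom in res:
            if atom.name == "CA" and atom.element.name == "C":
                if best is None or atom.occ > best.occ:
                    best = atom
        if best is None:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        aa = "X"
        if info is not None and info.is_amino_acid():
            aa = info.one_letter_code.upper()
        residues.append(
            Residue(
                index=len(residues) + 1,
                ca=np.array([best.pos.x, best.pos.y, best.pos.z]),
                aa=aa,
                resnum=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
            )
        )
    if not residues:
        raise ValueError(f"no backbone: chain {chain!r} has no C-alpha atoms")
    return residues


def _dssp_key(chain: str, resnum: int, icode: str) -> tuple[str, int | str]:
    return (chain, resnum) if not icode else (chain, f"{resnum}{icode}")


def read_dssp(path: str | Path) -> dict[tuple[str, int | str], tuple[str, int]]:
    """Parse a DSSP output file into ``(chain, residue) -> (ss, accessibility)``.

    Only the data block after the ``#  RESIDUE`` header is read.  Chain-break
    rows (``!`` in the amino-acid column) are skipped.  Blank secondary
    structure (coil) is normalised to ``-``; accessibility is the integer Å²
    of the ACC column.
    """
    text = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(text):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"not a DSSP file: {path}")

    out: dict[tuple[str, int | str], tuple[str, int]] = {}
    for line in text[start:]:
        if len(line) < 38 or line[13] == "!":
            continue
        resnum = int(line[5:10])
        icode = line[10].strip()
        chain = line[11]
        ss = line[16]
        if ss == " ":
            ss = "-"
        acc = int(line[34:38])
        out[_dssp_key(chain, resnum, icode)] = (ss, acc)
    return out


def read_ss_table(path: str | Path) -> dict[tuple[str, int | str], tuple[str, float]]:
    """Read a plain TSV annotation table (chain, resnum, ss, acc).

    This is the internal fallback annotation format written by
    ``sseforest simulate`` for synthetic fixtures.  It is *not* DSSP: no
    hydrogen-bond analysis is performed anywhere in this package; synthetic
    domains carry their secondary structure by construction.
    """
    out: dict[tuple[str, int | str], tuple[str, float]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("chain\t"):
            continue
        chain, resnum, ss, acc = line.split("\t")[:4]
        out[(chain, int(resnum))] = (ss, float(acc))
    return out


def annotate_residues(
    residues: Sequence[Residue],
    annotations: Mapping[tuple[str, int | str], tuple[str, float]],
    chain: str,
) -> list[Residue]:
    """Attach per-residue (ss, accessibility) annotations in place.

    Residues with no matching annotation row stay coil with accessibility 0.
    """
    for res in residues:
        key = _dssp_key(chain, res.resnum if res.resnum is not None else res.index,
                        res.icode)
        if key in annotations:
            ss, acc = annotations[key]
            res.ss_code = ss
            res.accessibility = float(acc)
    return list(residues)


def segment_sses(
    residues: Sequence[Residue],
    helix_codes: frozenset[str] = DEFAULT_HELIX_CODES,
    strand_codes: frozenset[str] = STRAND_CODES,
    min_helix: int = MIN_HELIX_LEN,
    min_strand: int = MIN_STRAND_LEN,
) -> list[SSE]:
    """Segment annotated residues into SSEs by maximal-run rules.

    Maximal runs of helix codes of length >= ``min_helix`` become helices;
    maximal runs of strand codes of length >= ``min_strand`` become strands.
    All other residues are coil.  Runs shorter than the minimum are dropped
    entirely (they produce no SSE).
    """
    def kind_of(r: Residue) -> str | None:
        if r.ss_code in helix_codes:
            return "helix"
        if r.ss_code in strand_codes:
            return "strand"
        return None

    sses: list[SSE] = []
    run: list[Residue] = []
    run_kind: str | None = None

    def flush() -> None:
        nonlocal run, run_kind
        if run_kind is not None:
            minimum = min_helix if run_kind == "helix" else min_strand
            if len(run) >= minimum:
                sses.append(
                    SSE(run_kind, run[0].index, run[-1].index, list(run))
                )
        run, run_kind = [], None

    for res in residues:
        k = kind_of(res)
        broken = run and res.index != run[-1].index + 1  # non-contiguous ordinals
        if k != run_kind or broken:
            flush()
            run_kind = k
        if k is not None:
            run.append(res)
    flush()
    return sses


def read_scop_cla(path: str | Path) -> list[ClaRecord]:
    """Read an ASTRAL dir.cla-style classification file.

    Lines are whitespace-separated ``sid pdb region sccs sunid [...]``;
    ``#`` comment lines and blank lines are skipped.  Malformed sccs or
    sunid fields raise with the offending line number.
    """
    from .scop_labels import parse_sccs  # validation only

    records: list[ClaRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 5:
            raise ValueError(f"line {lineno}: expected >=5 fields, got {len(fields)}")
        sid, pdb, region, sccs = fields[:4]
        try:
            parse_sccs(sccs)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        try:
            sunid = int(fields[4])
        except ValueError:
            raise ValueError(f"line {lineno}: sunid is not an integer: {fields[4]!r}") from None
        records.append(ClaRecord(sid, pdb, region, sccs, sunid))
    return records


def write_scop_cla(records: Iterable[ClaRecord], path: str | Path) -> None:
    """Write classification records back out in dir.cla layout."""
    lines = [f"{r.sid}\t{r.pdb}\t{r.region}\t{r.sccs}\t{r.sunid}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def _all_residues(domain: AnnotatedDomain) -> list[Residue]:
    if domain.residues is not None:
        return domain.residues
    return [r for sse in domain.sses for r in sse.residues]


def write_pdb(domain: AnnotatedDomain, path: str | Path, chain: str = "A") -> None:
    """Write a domain's Cα trace as a minimal single-chain PDB file.

    Residue numbers follow the domain ordinals; coil residues are included
    when the domain retains them.
    """
    from Bio.SeqUtils import seq3

    lines = []
    for serial, r in enumerate(_all_residues(domain), start=1):
        resname = seq3(r.aa).upper() if r.aa != "X" else "UNK"
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3s} {chain}{r.index:4d}    "
            f"{r.ca[0]:8.3f}{r.ca[1]:8.3f}{r.ca[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ss_table(domain: AnnotatedDomain, path: str | Path, chain: str = "A") -> None:
    """Write the per-residue (ss, accessibility) table read by
    :func:`read_ss_table` (synthetic-fixture annotation format, not DSSP)."""
    lines = ["chain\tresnum\tss\tacc"]
    for r in _all_residues(domain):
        lines.append(f"{chain}\t{r.index}\t{r.ss_code}\t{r.accessibility:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``id -> sequence`` map."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


T = TypeVar("T")


def filter_pairs_by_identity(
    pairs: Iterable[T],
    cutoff: float = IDENTITY_CUTOFF,
    identity: Callable[[T], float] = operator.attrgetter("identity"),
) -> list[T]:
    """Keep pairs with sequence identity strictly below ``cutoff``.

    ``identity`` extracts the identity fraction from each pair object
    (default: its ``identity`` attribute).  Identities must lie in [0, 1].
    """
    kept = []
    for p in pairs:
        ident = identity(p)
        if not 0.0 <= ident <= 1.0:
            raise ValueError(f"identity out of range: {ident}")
        if ident < cutoff:
            kept.append(p)
    return kept


def domain_to_json(domain: AnnotatedDomain) -> str:
    """Serialize a domain (sequence + SSEs with residues) to JSON text."""
    payload = {
        "id": domain.id,
        "sequence": domain.sequence,
        "sses": [
            {
                "kind": s.kind,
                "start": s.start,
                "end": s.end,
                "residues": [
                    {
                        "index": r.index,
                        "ca": [float(x) for x in r.ca],
                        "ss": r.ss_code,
                        "acc": r.accessibility,
                        "aa": r.aa,
                    }
                    for r in s.residues
                ],
            }
            for s in domain.sses
        ],
    }
    return json.dumps(payload, indent=1)


def domain_from_json(text: str) -> AnnotatedDomain:
    payload = json.loads(text)
    sses = [
        SSE(
            s["kind"],
            s["start"],
            s["end"],
            [
                Residue(
                    index=r["index"],
                    ca=np.array(r["ca"]),
                    ss_code=r["ss"],
                    accessibility=r["acc"],
                    aa=r["aa"],
                )
                for r in s["residues"]
            ],
        )
        for s in payload["sses"]
    ]
    return AnnotatedDomain(payload["id"], payload["sequence"], sses)
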