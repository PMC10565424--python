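"""Between-species mitochondrial target sites.

The diagnostic signal for assigning a low-coverage sample to one of two
closely related species is the set of positions where the two species'
mitochondrial reference genomes carry different bases.  This module builds
that site list from a global pairwise alignment of the two references,
classifies each substitution as a transition or a transversion (only
transversions are safe markers in ancient DNA, where post-mortem cytosine
deamination inflates C->T / G->A transitions), optionally removes positions
known to be polymorphic *within* either species, and exposes the coordinate
map between the two reference systems.

Coordinates are 0-based half-open everywhere in memory; all text output is
1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
DNA = frozenset("ACGT")
# IUPAC nucleotide codes accepted in input references (sites are only ever
# emitted at unambiguous ACGT columns).
IUPAC = frozenset("ACGTNRYSWKMBDHV")

SP1 = "SP1"
SP2 = "SP2"

#: refuse references longer than this; the tool targets organelle genomes
MAX_REFERENCE_LENGTH = 1_000_000


class SiteFileError(ValueError):
    """Raised when a site-list file cannot be parsed."""


@dataclass(frozen=True)
class ScoringParams:
    """Affine gap scoring for the reference-pair alignment.

    A gap of length L costs ``gap_open + L * gap_extend`` (both penalties
    are positive numbers).  The defaults are deliberately plain; the exact
    site counts obtained from a given reference pair depend on the scoring,
    which is why the scoring travels with every :class:`SiteSet` as
    provenance.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 10.0
    gap_extend: float = 4.0


@dataclass(frozen=True)
class ReferencePair:
    """Two single-contig reference sequences for the candidate species."""

    id_sp1: str
    id_sp2: str
    seq_sp1: str
    seq_sp2: str

    def __post_init__(self) -> None:
        if not self.seq_sp1 or not self.seq_sp2:
            raise ValueError("reference sequences must be non-empty")
        if self.id_sp1 == self.id_sp2:
            raise ValueError(
                f"species labels must be distinct (both {self.id_sp1!r})"
            )
        for label, seq in ((self.id_sp1, self.seq_sp1), (self.id_sp2, self.seq_sp2)):
            bad = set(seq) - IUPAC
            if bad:
                raise ValueError(
                    f"reference {label!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path_sp1: str | Path, path_sp2: str | Path) -> "ReferencePair":
        """Load a pair from two single-record FASTA files."""
        recs = []
        for path in (path_sp1, path_sp2):
            found = list(SeqIO.parse(str(path), "fasta"))
            if len(found) != 1:
                raise ValueError(
                    f"{path}: expected exactly one FASTA record, found {len(found)}"
                )
            recs.append(found[0])
        return cls(
            id_sp1=recs[0].id,
            id_sp2=recs[1].id,
            seq_sp1=str(recs[0].seq).upper(),
            seq_sp2=str(recs[1].seq).upper(),
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of the two references, as two gapped rows."""

    gapped_sp1: str
    gapped_sp2: str
    score: float
    scoring: ScoringParams

    def __post_init__(self) -> None:
        if len(self.gapped_sp1) != len(self.gapped_sp2):
            raise ValueError("gapped rows must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.gapped_sp1, self.gapped_sp2)):
            raise ValueError("alignment contains an all-gap column")

    @property
    def seq_sp1(self) -> str:
        return self.gapped_sp1.replace("-", "")

    @property
    def seq_sp2(self) -> str:
        return self.gapped_sp2.replace("-", "")


@dataclass(frozen=True)
class TargetSite:
    """One putative substitution between the two references.

    ``pos_sp1`` / ``pos_sp2`` are 0-based positions on each species' own
    reference.  ``subst_class`` is ``"transversion"`` iff exactly one of the
    two alleles is a purine.
    """

    pos_sp1: int
    pos_sp2: int
    allele_sp1: str
    allele_sp2: str
    subst_class: str
    polymorphic_sp1: bool = False
    polymorphic_sp2: bool = False

    def __post_init__(self) -> None:
        if self.allele_sp1 not in DNA or self.allele_sp2 not in DNA:
            raise ValueError("site alleles must be A/C/G/T")
        if self.allele_sp1 == self.allele_sp2:
            raise ValueError("site alleles must differ")
        expected = classify_substitution(self.allele_sp1, self.allele_sp2)
        if self.subst_class != expected:
            raise ValueError(
                f"subst_class {self.subst_class!r} inconsistent with alleles "
                f"{self.allele_sp1}/{self.allele_sp2} ({expected})"
            )


@dataclass(frozen=True)
class SiteSet:
    """An ordered collection of target sites plus its provenance.

    ``site_type`` 1 = all transversion substitutions between the references;
    ``site_type`` 2 = type 1 minus positions polymorphic within either
    species.  ``removed`` holds the sites dropped by the polymorphism filter
    (with their flags set); it is empty for type-1 sets.
    """

    sites: tuple[TargetSite, ...]
    site_type: int
    id_sp1: str
    id_sp2: str
    provenance: Mapping[str, object] = field(default_factory=dict)
    removed: tuple[TargetSite, ...] = ()

    def __post_init__(self) -> None:
        pos1 = [s.pos_sp1 for s in self.sites]
        if pos1 != sorted(pos1) or len(set(pos1)) != len(pos1):
            raise ValueError("sites must be strictly increasing on pos_sp1")
        pos2 = [s.pos_sp2 for s in self.sites]
        if len(set(pos2)) != len(pos2):
            raise ValueError("pos_sp2 values must be unique")
        if self.site_type == 2:
            if any(s.polymorphic_sp1 or s.polymorphic_sp2 for s in self.sites):
                raise ValueError("type-2 set retains a polymorphic site")
        elif self.site_type != 1:
            raise ValueError("site_type must be 1 or 2")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def positions(self, reference: str) -> dict[int, TargetSite]:
        """Map reference position -> site, in SP1 or SP2 coordinates."""
        if reference == SP1:
            return {s.pos_sp1: s for s in self.sites}
        if reference == SP2:
            return {s.pos_sp2: s for s in self.sites}
        raise ValueError(f"reference must be {SP1!r} or {SP2!r}, got {reference!r}")


@dataclass(frozen=True)
class CoordinateMap:
    """Bijective position map over the mutually aligned (non-gap) columns."""

    map_1to2: Mapping[int, int]
    map_2to1: Mapping[int, int]

    def to_sp2(self, pos_sp1: int) -> int | None:
        return self.map_1to2.get(pos_sp1)

    def to_sp1(self, pos_sp2: int) -> int | None:
        return self.map_2to1.get(pos_sp2)


def classify_substitution(a: str, b: str) -> str:
    """Classify an unordered base pair as ``transition`` or ``transversion``."""
    if a not in DNA or b not in DNA:
        raise ValueError(f"bases must be A/C/G/T, got {a!r}/{b!r}")
    if a == b:
        raise ValueError("bases are equal; not a substitution")
    pair = {a, b}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


def align_references(
    pair: ReferencePair,
    scoring: ScoringParams | None = None,
    max_length: int = MAX_REFERENCE_LENGTH,
) -> PairwiseAlignment:
    """Global (end-to-end) affine-gap alignment of the two references.

    Deterministic for fixed inputs: among co-optimal alignments the first
    traceback reported by Biopython's ``PairwiseAligner`` is taken.
    """
    scoring = scoring or ScoringParams()
    for label, seq in ((pair.id_sp1, pair.seq_sp1), (pair.id_sp2, pair.seq_sp2)):
        if len(seq) > max_length:
            raise ValueError(
                f"reference {label!r} has {len(seq)} bp, above the "
                f"{max_length} bp bound for organelle-scale alignment"
            )
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        # Biopython charges open_gap_score for the first gapped column and
        # extend_gap_score for each further one; with the convention that a
        # length-L gap costs gap_open + L * gap_extend the mapping is:
        open_gap_score=-(scoring.gap_open + scoring.gap_extend),
        extend_gap_score=-scoring.gap_extend,
    )
    aln = aligner.align(pair.seq_sp1, pair.seq_sp2)[0]
    return PairwiseAlignment(
        gapped_sp1=str(aln[0]),
        gapped_sp2=str(aln[1]),
        score=float(aln.score),
        scoring=scoring,
    )


def extract_substitutions(aln: PairwiseAlignment) -> list[TargetSite]:
    """One site per column where both rows carry differing A/C/G/T bases.

    Columns containing a gap or any ambiguity code yield no site.  Positions
    are 0-based indices into each ungapped reference.
    """
    sites: list[TargetSite] = []
    p1 = p2 = 0
    for a, b in zip(aln.gapped_sp1, aln.gapped_sp2):
        if a != "-" and b != "-" and a != b and a in DNA and b in DNA:
            sites.append(
                TargetSite(
                    pos_sp1=p1,
                    pos_sp2=p2,
                    allele_sp1=a,
                    allele_sp2=b,
                    subst_class=classify_substitution(a, b),
                )
            )
        if a != "-":
            p1 += 1
        if b != "-":
            p2 += 1
    return sites


def build_site_set(
    pair: ReferencePair,
    scoring: ScoringParams | None = None,
    transversions_only: bool = True,
    alignment: PairwiseAlignment | None = None,
) -> SiteSet:
    """Align the pair and return the type-1 target site set.

    Pass ``alignment`` to reuse a previously computed alignment of the
    same pair (it must degap to the pair's sequences).
    """
    scoring = scoring or ScoringParams()
    if alignment is not None:
        if (alignment.seq_sp1, alignment.seq_sp2) != (pair.seq_sp1, pair.seq_sp2):
            raise ValueError("alignment does not correspond to this pair")
        aln = alignment
        scoring = alignment.scoring
    else:
        aln = align_references(pair, scoring)
    sites = extract_substitutions(aln)
    n_subst = len(sites)
    if transversions_only:
        sites = [s for s in sites if s.subst_class == "transversion"]
    return SiteSet(
        sites=tuple(sites),
        site_type=1,
        id_sp1=pair.id_sp1,
        id_sp2=pair.id_sp2,
        provenance={
            "scoring": dataclasses.asdict(scoring),
            "alignment_score": aln.score,
            "n_substitutions": n_subst,
            "transversions_only": transversions_only,
        },
    )


def find_polymorphic_positions(
    species_sequences: Iterable[str], ref_length: int
) -> set[int]:
    """Positions where a within-species panel shows >=2 distinct bases.

    Each panel sequence must already be expressed in reference coordinates
    (same length as the reference); gaps, ``N`` and any other non-ACGT
    character count as missing data.
    """
    observed: dict[int, set[str]] = {}
    for i, seq in enumerate(species_sequences):
        seq = seq.upper()
        if len(seq) != ref_length:
            raise ValueError(
                f"panel sequence {i} has length {len(seq)}, expected {ref_length}"
            )
        for pos, base in enumerate(seq):
            if base in DNA:
                observed.setdefault(pos, set()).add(base)
    return {pos for pos, bases in observed.items() if len(bases) >= 2}


def filter_polymorphic(
    sites: SiteSet, poly_sp1: set[int], poly_sp2: set[int]
) -> SiteSet:
    """Drop sites polymorphic within either species; returns a type-2 set.

    The removed sites are kept (with their polymorphism flags set) in the
    result's ``removed`` attribute, so ``len(result) + len(result.removed)``
    always equals ``len(sites)``.
    """
    kept: list[TargetSite] = []
    removed: list[TargetSite] = []
    for s in sites:
        in1 = s.pos_sp1 in poly_sp1
        in2 = s.pos_sp2 in poly_sp2
        if in1 or in2:
            removed.append(
                dataclasses.replace(s, polymorphic_sp1=in1, polymorphic_sp2=in2)
            )
        else:
            kept.append(s)
    provenance = dict(sites.provenance)
    provenance["polymorphism_filter"] = {
        "n_poly_sp1": len(poly_sp1),
        "n_poly_sp2": len(poly_sp2),
        "n_removed": len(removed),
    }
    return SiteSet(
        sites=tuple(kept),
        site_type=2,
        id_sp1=sites.id_sp1,
        id_sp2=sites.id_sp2,
        provenance=provenance,
        removed=tuple(removed),
    )


def coordinate_map(aln: PairwiseAlignment) -> CoordinateMap:
    """Position map between the two references over mutually non-gap columns."""
    m12: dict[int, int] = {}
    m21: dict[int, int] = {}
    p1 = p2 = 0
    for a, b in zip(aln.gapped_sp1, aln.gapped_sp2):
        if a != "-" and b != "-":
            m12[p1] = p2
            m21[p2] = p1
        if a != "-":
            p1 += 1
        if b != "-":
            p2 += 1
    return CoordinateMap(map_1to2=m12, map_2to1=m21)


_SITE_COLUMNS = ("pos_sp1", "allele_sp1", "pos_sp2", "allele_sp2",
                 "class", "poly_sp1", "poly_sp2")


def write_site_set(sites: SiteSet, path: str | Path) -> None:
    """Write a site set as TSV (1-based positions, ``#``-commented header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# site_type={sites.site_type}\n")
        fh.write(f"# sp1={sites.id_sp1}\tsp2={sites.id_sp2}\n")
        for key, val in sites.provenance.items():
            fh.write(f"# {key}={val!r}\n")
        fh.write("#" + "\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.pos_sp1 + 1}\t{s.allele_sp1}\t{s.pos_sp2 + 1}\t"
                f"{s.allele_sp2}\t{s.subst_class}\t"
                f"{int(s.polymorphic_sp1)}\t{int(s.polymorphic_sp2)}\n"
            )


def read_site_set(path: str | Path) -> SiteSet:
    """Read a site set written by :func:`write_site_set`."""
    path = Path(path)
    site_type = 1
    id_sp1, id_sp2 = SP1, SP2
    sites: list[TargetSite] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*site_type=(\d+)", line)
                if m:
                    site_type = int(m.group(1))
                m = re.match(r"#\s*sp1=(\S+)\tsp2=(\S+)", line)
                if m:
                    id_sp1, id_sp2 = m.group(1), m.group(2)
                continue
            fields = line.split("\t")
            if len(fields) != len(_SITE_COLUMNS):
                raise SiteFileError(
                    f"{path}:{lineno}: expected {len(_SITE_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                pos1, pos2 = int(fields[0]), int(fields[2])
            except ValueError as exc:
                raise SiteFileError(
                    f"{path}:{lineno}: non-numeric position: {exc}"
                ) from None
            try:
                sites.append(
                    TargetSite(
                        pos_sp1=pos1 - 1,
                        pos_sp2=pos2 - 1,
                        allele_sp1=fields[1],
                        allele_sp2=fields[3],
                        subst_class=fields[4],
                        polymorphic_sp1=bool(int(fields[5])),
                        polymorphic_sp2=bool(int(fields[6])),
                    )
                )
            except ValueError as exc:
                raise SiteFileError(f"{path}:{lineno}: {exc}") from None
    return SiteSet(
        sites=tuple(sites),
        site_type=site_type,
        id_sp1=id_sp1,
        id_sp2=id_sp2,
        provenance={"source_file": str(path)},
    )
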