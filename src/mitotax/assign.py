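"""Per-read species labelling at target sites.

A read aligned to the SP1 reference should carry the SP1 allele at every
target site it covers; if it actually derives from SP2 it will carry the
SP2 (alternative) allele instead.  Each read is therefore labelled from
the alleles it shows at the target sites it overlaps, pooled over its
alignments to one or both references:

* ``SP1``   — at least one informative observation, all supporting SP1;
* ``SP2``   — symmetric;
* ``inconsistent`` — informative observations supporting both species
  (excluded from counting: plausible PCR/sequencing error, homoplasy or
  incomplete lineage sorting);
* ``uninformative`` — no informative observation (third alleles, low base
  quality, or no site covered).

Observations of a third allele (neither species' base) are treated as
non-evidence rather than as inconsistency: a single sequencing error at a
transversion site should not discard an otherwise consistent read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .bamfilter import ReadRecord
from .refsites import SP1, SP2, SiteSet, TargetSite

LABEL_SP1 = SP1
LABEL_SP2 = SP2
LABEL_INCONSISTENT = "inconsistent"
LABEL_UNINFORMATIVE = "uninformative"

DEFAULT_MIN_BASE_QUAL = 13


@dataclass(frozen=True)
class SiteObservation:
    """The base a read shows at one target site, on one reference."""

    site: TargetSite
    observed_base: str
    base_qual: int
    source_reference: str

    def __post_init__(self) -> None:
        if self.observed_base not in "ACGTN":
            raise ValueError(f"observed base {self.observed_base!r} not in ACGTN")
        if self.source_reference not in (SP1, SP2):
            raise ValueError("source_reference must be SP1 or SP2")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    observations: tuple[SiteObservation, ...]
    label: str


def support_of(obs: SiteObservation) -> str | None:
    """Which species the observed allele supports (None for third alleles).

    The rule is reference-symmetric: seeing ``allele_sp1`` supports SP1 and
    seeing ``allele_sp2`` supports SP2, whichever reference the read was
    aligned to.
    """
    if obs.observed_base == obs.site.allele_sp1:
        return SP1
    if obs.observed_base == obs.site.allele_sp2:
        return SP2
    return None


def pileup_site_alleles(
    reads: Iterable[ReadRecord],
    sites: SiteSet,
    reference: str,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
    reference_length: int | None = None,
) -> dict[str, list[SiteObservation]]:
    """Collect each read's bases at the target sites it covers.

    ``reference`` selects the coordinate system (``SP1`` or ``SP2``) the
    reads are aligned to.  Deletions, N calls and bases below
    ``min_base_qual`` yield no observation.  Reads covering no site are
    omitted from the result.
    """
    site_at = sites.positions(reference)
    if reference_length is not None:
        beyond = [p for p in site_at if p >= reference_length]
        if beyond:
            raise ValueError(
                f"site position {max(beyond)} beyond reference length "
                f"{reference_length}"
            )
    out: dict[str, list[SiteObservation]] = {}
    for r in reads:
        hits = []
        for qpos, rpos in r.aligned_pairs():
            site = site_at.get(rpos)
            if site is None:
                continue
            base = r.query_bases[qpos]
            qual = r.base_quals[qpos]
            if base == "N" or qual < min_base_qual:
                continue
            hits.append(
                SiteObservation(
                    site=site,
                    observed_base=base,
                    base_qual=qual,
                    source_reference=reference,
                )
            )
        if hits:
            out.setdefault(r.read_id, []).extend(hits)
    return out


def label_read(read_id: str, observations: Sequence[SiteObservation]) -> ReadAssignment:
    """Label one read from its pooled observations (one or both references)."""
    supports = {s for s in (support_of(o) for o in observations) if s is not None}
    if not supports:
        label = LABEL_UNINFORMATIVE
    elif supports == {SP1}:
        label = LABEL_SP1
    elif supports == {SP2}:
        label = LABEL_SP2
    else:
        label = LABEL_INCONSISTENT
    return ReadAssignment(
        read_id=read_id, observations=tuple(observations), label=label
    )


def select_read_universe(
    mode: str,
    ids_sp1: Iterable[str],
    ids_sp2: Iterable[str] | None,
) -> set[str]:
    """Which read ids to evaluate.

    ``all`` (default): reads passing filters on either reference.
    ``shared``: only reads aligned to both references — a conservative
    variant that cancels reference-quality asymmetry at the cost of power.
    """
    s1 = set(ids_sp1)
    if mode == "all":
        return s1 | (set(ids_sp2) if ids_sp2 is not None else set())
    if mode == "shared":
        if ids_sp2 is None:
            raise ValueError("shared mode requires alignments to both references")
        s2 = set(ids_sp2)
        shared = s1 & s2
        if not shared and (s1 or s2):
            import warnings

            warnings.warn(
                "shared-mode intersection is empty; are read ids comparable "
                "across the two alignments?",
                stacklevel=2,
            )
        return shared
    raise ValueError(f"mode must be 'all' or 'shared', got {mode!r}")


def assign_reads(
    obs_sp1: Mapping[str, Sequence[SiteObservation]],
    obs_sp2: Mapping[str, Sequence[SiteObservation]] | None,
    mode: str = "all",
    universe: set[str] | None = None,
) -> list[ReadAssignment]:
    """Pool per-reference observations and label every read in the universe.

    ``universe`` defaults to the ids appearing in the observation maps,
    restricted per ``mode``; pass the id sets from *filtering* (via
    :func:`select_read_universe`) to also count reads that overlap no site.
    """
    if universe is None:
        universe = select_read_universe(
            mode, obs_sp1.keys(), obs_sp2.keys() if obs_sp2 is not None else None
        )
    out = []
    for rid in sorted(universe):
        pooled = list(obs_sp1.get(rid, ()))
        if obs_sp2 is not None:
            pooled.extend(obs_sp2.get(rid, ()))
        out.append(label_read(rid, pooled))
    return out


def count_labels(assignments: Iterable[ReadAssignment]) -> dict[str, int]:
    counts = {
        LABEL_SP1: 0,
        LABEL_SP2: 0,
        LABEL_INCONSISTENT: 0,
        LABEL_UNINFORMATIVE: 0,
    }
    for a in assignments:
        counts[a.label] += 1
    return counts
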