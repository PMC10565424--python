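"""End-to-end composition: filtered reads -> assignments -> verdict.

Glue shared by the command-line ``classify`` command and the simulation
sweeps: apply the read filters to the alignments against each reference,
pick the read universe, genotype the target sites, label reads and run
the binomial decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from . import assign as assign_mod
from .assign import DEFAULT_MIN_BASE_QUAL
from .bamfilter import FilterConfig, ReadRecord, dedup_endpoints, filter_reads
from .decide import DEFAULT_ALPHA, ClassificationResult, classify_sample
from .refsites import SP1, SP2, SiteSet


@dataclass(frozen=True)
class ClassifyOutcome:
    result: ClassificationResult
    assignments: tuple[assign_mod.ReadAssignment, ...]
    n_reads_sp1: int  # reads surviving filters on each reference
    n_reads_sp2: int


def classify_read_sets(
    reads_sp1: Iterable[ReadRecord] | None,
    reads_sp2: Iterable[ReadRecord] | None,
    sites: SiteSet,
    mode: str = "all",
    filters: FilterConfig | None = None,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
    alpha: float = DEFAULT_ALPHA,
) -> ClassifyOutcome:
    """Run the full decision pipeline on alignments to one or both references."""
    filters = filters or FilterConfig()
    if reads_sp1 is None and reads_sp2 is None:
        raise ValueError("at least one read set is required")
    if mode == "shared" and (reads_sp1 is None or reads_sp2 is None):
        raise ValueError("shared mode requires alignments to both references")

    def prep(reads: Iterable[ReadRecord] | None) -> list[ReadRecord]:
        if reads is None:
            return []
        kept = filter_reads(reads, filters)
        return dedup_endpoints(kept) if filters.dedup else list(kept)

    kept_sp1 = prep(reads_sp1)
    kept_sp2 = prep(reads_sp2)
    obs_sp1 = assign_mod.pileup_site_alleles(kept_sp1, sites, SP1, min_base_qual)
    obs_sp2 = assign_mod.pileup_site_alleles(kept_sp2, sites, SP2, min_base_qual)
    universe = assign_mod.select_read_universe(
        mode,
        (r.read_id for r in kept_sp1),
        (r.read_id for r in kept_sp2) if reads_sp2 is not None else None,
    )
    assignments = assign_mod.assign_reads(
        obs_sp1, obs_sp2 if reads_sp2 is not None else None, mode, universe
    )
    counts = assign_mod.count_labels(assignments)
    result = classify_sample(
        n_sp1=counts[assign_mod.LABEL_SP1],
        n_sp2=counts[assign_mod.LABEL_SP2],
        n_inconsistent=counts[assign_mod.LABEL_INCONSISTENT],
        alpha=alpha,
        mode=mode,
        site_type=sites.site_type,
    )
    return ClassifyOutcome(
        result=result,
        assignments=tuple(assignments),
        n_reads_sp1=len(kept_sp1),
        n_reads_sp2=len(kept_sp2),
    )
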