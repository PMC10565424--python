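"""Read-level filtering and summary statistics for aDNA alignments.

Ancient-DNA pipelines discard unreliable alignments before genotyping:
PCR duplicates (recognised by identical mapping endpoints), reads with low
mapping quality (default MAPQ < 30), very short reads (< 35 bp) and reads
with a high mismatch fraction (> 10%).  This module implements those
filters on a light-weight read record, plus Bernoulli downsampling,
terminal C->T / G->A damage profiling (used to authenticate non-UDG
ancient libraries) and comparative-alignment summary counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# CIGAR operation codes (pysam numeric convention)
_CONSUMES_QUERY = {0, 1, 4, 7, 8}   # M, I, S, =, X
_CONSUMES_REF = {0, 2, 3, 7, 8}     # M, D, N, =, X
_ALIGNED = {0, 7, 8}                # M, =, X
_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
_OP_CHAR = {v: k for k, v in _OP_CODE.items()}


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read with the metadata the filters and genotyper need.

    ``start``/``end`` are the 0-based half-open reference span.  ``nm`` is
    the edit distance (mismatches plus inserted/deleted bases, as in the
    standard NM tag); ``None`` if the source alignment lacked it.
    ``query_bases`` and ``base_quals`` are stored in reference orientation,
    exactly as in a SAM record.
    """

    read_id: str
    reference_label: str
    start: int
    end: int
    strand: str
    mapq: int
    cigar: tuple[tuple[int, int], ...]
    query_bases: str
    base_quals: tuple[int, ...]
    nm: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        qlen = sum(n for op, n in self.cigar if op in _CONSUMES_QUERY)
        if qlen != len(self.query_bases):
            raise ValueError("CIGAR query length inconsistent with bases")
        rlen = sum(n for op, n in self.cigar if op in _CONSUMES_REF)
        if rlen != self.end - self.start:
            raise ValueError("CIGAR reference length inconsistent with span")

    @property
    def aligned_length(self) -> int:
        """Number of match-state (M/=/X) bases."""
        return sum(n for op, n in self.cigar if op in _ALIGNED)

    @property
    def indel_bases(self) -> int:
        return sum(n for op, n in self.cigar if op in (1, 2))

    @property
    def mismatches(self) -> int | None:
        """Substitution count: NM minus inserted/deleted bases."""
        if self.nm is None:
            return None
        return self.nm - self.indel_bases

    @property
    def cigarstring(self) -> str:
        return "".join(f"{n}{_OP_CHAR[op]}" for op, n in self.cigar)

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_pos, ref_pos) for every match-state base."""
        q = r = 0
        for op, n in self.cigar:
            if op in _ALIGNED:
                for i in range(n):
                    yield q + i, self.start + r + i
            if op in _CONSUMES_QUERY:
                q += n
            if op in _CONSUMES_REF:
                r += n

    def base_at(self, ref_pos: int) -> tuple[str, int] | None:
        """Read base and quality aligned at ``ref_pos``, or None (gap/off-read)."""
        for qpos, rpos in self.aligned_pairs():
            if rpos == ref_pos:
                return self.query_bases[qpos], self.base_quals[qpos]
        return None

    @classmethod
    def from_pysam(
        cls, seg: pysam.AlignedSegment, reference_label: str
    ) -> "ReadRecord":
        nm = seg.get_tag("NM") if seg.has_tag("NM") else None
        quals = seg.query_qualities
        return cls(
            read_id=seg.query_name,
            reference_label=reference_label,
            start=seg.reference_start,
            end=seg.reference_end,
            strand="-" if seg.is_reverse else "+",
            mapq=seg.mapping_quality,
            cigar=tuple(seg.cigartuples),
            query_bases=seg.query_sequence,
            base_quals=tuple(quals) if quals is not None else (0,) * len(seg.query_sequence),
            nm=int(nm) if nm is not None else None,
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the standard aDNA read filters."""

    min_mapq: int = 30
    min_length: int = 35
    max_mismatch_frac: float = 0.10
    dedup: bool = True
    missing_nm_policy: str = "drop"  # or "keep"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mismatch_frac <= 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1]")
        if self.missing_nm_policy not in ("drop", "keep"):
            raise ValueError("missing_nm_policy must be 'drop' or 'keep'")


#: preset matching the modern-equid workflow, which relaxes MAPQ to 20
MODERN_EQUID_FILTERS = FilterConfig(min_mapq=20)


@dataclass
class DamageProfile:
    """Terminal deamination mismatch frequencies.

    ``ct_5prime[i]`` is the frequency of reference-C read-T at read position
    i+1 from the 5' end (in the original read orientation); ``ga_3prime``
    mirrors this for G->A from the 3' end.  Entries are ``nan`` where no
    opportunity (reference C resp. G) was observed.
    """

    ct_5prime: np.ndarray
    ga_3prime: np.ndarray
    n_reads: int


@dataclass(frozen=True)
class CompStats:
    """Comparative-alignment totals for one BAM."""

    total_aligned_bases: int
    mismatch_count: int

    @property
    def mismatch_proportion(self) -> float:
        if self.total_aligned_bases == 0:
            return float("nan")
        return self.mismatch_count / self.total_aligned_bases


def read_alignments(
    path: str | Path, reference_label: str, mode: str | None = None
) -> Iterator[ReadRecord]:
    """Stream mapped primary alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for seg in bam.fetch(until_eof=True):
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            yield ReadRecord.from_pysam(seg, reference_label)


def write_alignments(
    reads: Iterable[ReadRecord],
    path: str | Path,
    reference_name: str,
    reference_length: int,
) -> None:
    """Write records to SAM or BAM (by extension), sorted by position."""
    path = Path(path)
    mode = "wb" if path.suffix == ".bam" else "w"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    reads = sorted(reads, key=lambda r: (r.start, r.end, r.read_id))
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.query_bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_quals)
            )
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.mapping_quality = r.mapq
            seg.cigartuples = r.cigar
            seg.flag = 16 if r.strand == "-" else 0
            if r.nm is not None:
                seg.set_tag("NM", r.nm)
            out.write(seg)


def filter_reads(
    reads: Iterable[ReadRecord], cfg: FilterConfig | None = None
) -> Iterator[ReadRecord]:
    """Apply the MAPQ / length / mismatch-fraction filters, preserving order."""
    cfg = cfg or FilterConfig()
    for r in reads:
        if r.mapq < cfg.min_mapq:
            continue
        if r.aligned_length < cfg.min_length:
            continue
        mm = r.mismatches
        if mm is None:
            if cfg.missing_nm_policy == "drop":
                warnings.warn(
                    f"read {r.read_id}: no NM tag; dropped "
                    "(missing_nm_policy='drop')",
                    stacklevel=2,
                )
                continue
        elif r.aligned_length > 0 and mm / r.aligned_length > cfg.max_mismatch_frac:
            continue
        yield r


def dedup_endpoints(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Collapse PCR duplicates: reads sharing (reference, start, end, strand).

    One representative is kept per group: the read with the highest total
    base quality, ties broken by the lexicographically smallest read id.
    Output order follows the first appearance of each group.
    """
    best: dict[tuple, ReadRecord] = {}
    order: list[tuple] = []
    for r in reads:
        key = (r.reference_label, r.start, r.end, r.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = r
            order.append(key)
        else:
            rq, cq = sum(r.base_quals), sum(cur.base_quals)
            if rq > cq or (rq == cq and r.read_id < cur.read_id):
                best[key] = r
    return [best[k] for k in order]


def downsample(
    reads: Iterable[ReadRecord], fraction: float, seed: int
) -> list[ReadRecord]:
    """Keep each read independently with probability ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return [r for r in reads if rng.random() < fraction]


def damage_profile(
    reads: Iterable[ReadRecord], reference: str, k: int = 10
) -> DamageProfile:
    """Measure terminal C->T (5') and G->A (3') mismatch frequencies.

    Works in the original read orientation: for reverse-strand alignments
    the stored sequence is reverse-complemented back, so a post-mortem
    deamination always appears as C->T near the 5' end and G->A near the
    3' end regardless of mapping strand.
    """
    ct_opp = np.zeros(k, dtype=int)   # reference C seen at 5' offset
    ct_hit = np.zeros(k, dtype=int)   # ... read as T
    ga_opp = np.zeros(k, dtype=int)
    ga_hit = np.zeros(k, dtype=int)
    n_reads = 0
    for r in reads:
        n_reads += 1
        qlen = len(r.query_bases)
        for qpos, rpos in r.aligned_pairs():
            ref_base = reference[rpos]
            read_base = r.query_bases[qpos]
            if r.strand == "-":
                from_5p = qlen - 1 - qpos
                ref_base = ref_base.translate(COMPLEMENT)
                read_base = read_base.translate(COMPLEMENT)
            else:
                from_5p = qpos
            from_3p = qlen - 1 - from_5p
            if from_5p < k and ref_base == "C":
                ct_opp[from_5p] += 1
                if read_base == "T":
                    ct_hit[from_5p] += 1
            if from_3p < k and ref_base == "G":
                ga_opp[from_3p] += 1
                if read_base == "A":
                    ga_hit[from_3p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(ct_opp > 0, ct_hit / np.maximum(ct_opp, 1), np.nan)
        ga = np.where(ga_opp > 0, ga_hit / np.maximum(ga_opp, 1), np.nan)
    return DamageProfile(ct_5prime=ct, ga_3prime=ga, n_reads=n_reads)


def comp_stats(reads: Iterable[ReadRecord]) -> CompStats:
    """Total aligned bases and substitution mismatches over a read set."""
    total = 0
    mismatches = 0
    for r in reads:
        total += r.aligned_length
        mm = r.mismatches
        if mm is not None:
            mismatches += mm
    return CompStats(total_aligned_bases=total, mismatch_count=mismatches)
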