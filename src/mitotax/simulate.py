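"""Synthetic reference pairs and ancient-like mitochondrial read sets.

Two generators drive development and evaluation without any external data
or aligner:

* :func:`make_reference_pair` plants a controlled number of transversions,
  transitions and short indels into a random mitochondrial-sized sequence,
  returning the derived second reference together with the exact truth
  list of substitution sites.

* :func:`simulate_reads` draws short fragments from a reference to a
  target fold-coverage, flips a coin for strand, applies post-mortem
  deamination (C->T from the 5' end, G->A from the 3' end, exponentially
  decaying into the read — the double-strand damage signature) and then
  uniform sequencing error, recording every edit so tests can check the
  pipeline against ground truth.  Reads come back both as FASTQ-style
  records and as alignment records placed at their true positions, so the
  downstream modules consume them exactly as they would consume a real
  alignment.

:func:`project_reads` re-expresses truth alignments against the *other*
reference through the coordinate map, replacing the external re-alignment
step of a real workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .bamfilter import COMPLEMENT, ReadRecord
from .refsites import (
    SP1,
    SP2,
    CoordinateMap,
    ReferencePair,
    TargetSite,
    classify_substitution,
)

DNA = "ACGT"
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: default length of a synthetic mitochondrial reference (sheep mtDNA scale)
DEFAULT_MT_LENGTH = 16_616


@dataclass(frozen=True)
class FragmentModel:
    """Lognormal fragment lengths truncated to a plausible aDNA range.

    Defaults give a median of ~65 bp within [35, 150] bp, the short-
    fragment regime typical of degraded ancient libraries.
    """

    mean_log: float = math.log(65.0)
    sd_log: float = 0.35
    min_len: int = 35
    max_len: int = 150

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")

    def draw(self, rng: np.random.Generator) -> int:
        while True:
            length = int(round(rng.lognormal(self.mean_log, self.sd_log)))
            if self.min_len <= length <= self.max_len:
                return length


@dataclass(frozen=True)
class DamageModel:
    """Double-strand terminal deamination.

    C->T at 5'-end position i (1-based) with probability
    ``d_max5 * exp(-decay * (i - 1))``; G->A mirrored from the 3' end.
    Defaults exceed the >20% terminal-damage threshold used to
    authenticate non-UDG ancient libraries.
    """

    d_max5: float = 0.3
    d_max3: float = 0.3
    decay: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.d_max5 <= 1 and 0 <= self.d_max3 <= 1):
            raise ValueError("damage rates must be in [0, 1]")

    def rate_5p(self, i_from_5p: int) -> float:
        return self.d_max5 * math.exp(-self.decay * i_from_5p)

    def rate_3p(self, i_from_3p: int) -> float:
        return self.d_max3 * math.exp(-self.decay * i_from_3p)


@dataclass(frozen=True)
class SimConfig:
    """Everything one simulated sample needs."""

    source_species: str = SP1
    target_coverage: float = 1.0
    fragments: FragmentModel = field(default_factory=FragmentModel)
    damage: DamageModel = field(default_factory=DamageModel)
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_coverage < 0:
            raise ValueError("target_coverage must be >= 0")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimRead:
    """One simulated fragment with its full truth record.

    ``sequence``/``quals`` are in the original (sequencing) orientation;
    ``start`` is the true 0-based position on the source reference and
    ``strand`` tells whether the fragment was drawn from the reverse
    strand.  ``damage_edits`` and ``error_edits`` list read positions
    (5'-based) where an edit was applied.
    """

    read_id: str
    start: int
    strand: str
    sequence: str
    quals: tuple[int, ...]
    damage_edits: tuple[int, ...]
    error_edits: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)


def make_reference_pair(
    length: int,
    n_transversions: int,
    n_transitions: int,
    n_indels: int = 0,
    seed: int = 0,
    id_sp1: str = "SYN1",
    id_sp2: str = "SYN2",
    indel_max_len: int = 3,
    gc: float = 0.45,
) -> tuple[ReferencePair, list[TargetSite]]:
    """Random reference plus a derived partner with planted edits.

    Returns the pair and the truth list of planted substitution sites
    (positions in each reference's own coordinates, indel-aware).  Edit
    positions are distinct and never adjacent to an indel, so the truth
    list is unambiguous.
    """
    rng = np.random.default_rng(seed)
    n_edits = n_transversions + n_transitions + n_indels
    if n_edits * (indel_max_len + 2) > length:
        raise ValueError("too many edits for the requested length")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq1 = "".join(rng.choice(list(DNA), size=length, p=p))

    # distinct positions with pairwise gaps > indel_max_len + 1, drawn
    # uniformly by the stars-and-bars shift trick
    min_gap = indel_max_len + 2
    slack = length - indel_max_len - 1 - (n_edits - 1) * (min_gap - 1)
    if n_edits > 0 and slack < n_edits:
        raise ValueError("too many edits for the requested length")
    raw = np.sort(rng.choice(slack, size=n_edits, replace=False))
    pos = raw + np.arange(n_edits) * (min_gap - 1)
    kinds = (
        ["tv"] * n_transversions + ["ts"] * n_transitions + ["indel"] * n_indels
    )
    rng.shuffle(kinds)

    out: list[str] = []
    truth: list[TargetSite] = []
    cursor = 0
    offset = 0  # pos_sp2 - pos_sp1 running difference
    for p1, kind in zip(pos, kinds):
        p1 = int(p1)
        out.append(seq1[cursor:p1])
        base = seq1[p1]
        if kind == "tv":
            alt = str(rng.choice(list(TRANSVERSIONS_OF[base])))
            out.append(alt)
            truth.append(
                TargetSite(
                    pos_sp1=p1,
                    pos_sp2=p1 + offset,
                    allele_sp1=base,
                    allele_sp2=alt,
                    subst_class="transversion",
                )
            )
            cursor = p1 + 1
        elif kind == "ts":
            alt = TRANSITION_OF[base]
            out.append(alt)
            truth.append(
                TargetSite(
                    pos_sp1=p1,
                    pos_sp2=p1 + offset,
                    allele_sp1=base,
                    allele_sp2=alt,
                    subst_class="transition",
                )
            )
            cursor = p1 + 1
        else:  # indel: delete or insert 1..indel_max_len bases in sp2
            ilen = int(rng.integers(1, indel_max_len + 1))
            if rng.random() < 0.5:  # deletion from sp2
                cursor = p1 + ilen
                offset -= ilen
            else:  # insertion into sp2
                out.append("".join(rng.choice(list(DNA), size=ilen)))
                cursor = p1
                offset += ilen
    out.append(seq1[cursor:])
    seq2 = "".join(out)
    pair = ReferencePair(id_sp1=id_sp1, id_sp2=id_sp2, seq_sp1=seq1, seq_sp2=seq2)
    return pair, truth


def _revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def simulate_reads(
    reference: str,
    cfg: SimConfig,
    read_prefix: str = "sim",
) -> tuple[list[SimRead], list[ReadRecord]]:
    """Draw ancient-like fragments until the target coverage is reached.

    Returns the truth reads (original orientation, with edit lists) and
    ready-made alignment records against the source reference (reference
    orientation, full-length match CIGAR, correct NM, constant Q30 base
    qualities).
    """
    rng = np.random.default_rng(cfg.seed)
    length = len(reference)
    target_bases = cfg.target_coverage * length
    sim_reads: list[SimRead] = []
    records: list[ReadRecord] = []
    total = 0
    idx = 0
    while total < target_bases:
        flen = cfg.fragments.draw(rng)
        if flen > length:
            flen = length
        start = int(rng.integers(0, length - flen + 1))
        fragment = reference[start : start + flen]
        strand = "-" if rng.random() < 0.5 else "+"
        read = fragment if strand == "+" else _revcomp(fragment)

        bases = list(read)
        damage_edits: list[int] = []
        for i in range(flen):
            if bases[i] == "C" and rng.random() < cfg.damage.rate_5p(i):
                bases[i] = "T"
                damage_edits.append(i)
        for j in range(flen):
            i = flen - 1 - j
            if bases[i] == "G" and rng.random() < cfg.damage.rate_3p(j):
                bases[i] = "A"
                damage_edits.append(i)
        error_edits: list[int] = []
        for i in range(flen):
            if rng.random() < cfg.error_rate:
                alts = [c for c in DNA if c != bases[i]]
                bases[i] = str(rng.choice(alts))
                error_edits.append(i)
        read_seq = "".join(bases)
        read_id = f"{read_prefix}_{cfg.source_species}_{idx:06d}"
        quals = (30,) * flen
        sim_reads.append(
            SimRead(
                read_id=read_id,
                start=start,
                strand=strand,
                sequence=read_seq,
                quals=quals,
                damage_edits=tuple(sorted(damage_edits)),
                error_edits=tuple(error_edits),
            )
        )
        stored = read_seq if strand == "+" else _revcomp(read_seq)
        nm = sum(1 for a, b in zip(stored, fragment) if a != b)
        records.append(
            ReadRecord(
                read_id=read_id,
                reference_label=cfg.source_species,
                start=start,
                end=start + flen,
                strand=strand,
                mapq=37,
                cigar=((0, flen),),
                query_bases=stored,
                base_quals=quals,
                nm=nm,
            )
        )
        total += flen
        idx += 1
    return sim_reads, records


def project_reads(
    records: Iterable[ReadRecord],
    cmap: CoordinateMap,
    target_reference: str,
    target_label: str,
) -> tuple[list[ReadRecord], int]:
    """Re-express truth alignments in the other reference's coordinates.

    Every reference position of a read is pushed through the coordinate
    map; unmapped source positions become insertions, holes in the target
    positions become deletions, and NM is recomputed against the target
    sequence.  Reads whose span maps nowhere are dropped; the second
    return value counts them.
    """
    forward = cmap.to_sp2 if target_label == SP2 else cmap.to_sp1
    out: list[ReadRecord] = []
    dropped = 0
    for r in records:
        # per source position in the read span: target position or None
        mapped = [forward(p) for p in range(r.start, r.end)]
        if all(m is None for m in mapped):
            dropped += 1
            continue
        # build CIGAR walking the read; leading/trailing unmapped source
        # positions are soft-clipped rather than inserted
        first = next(i for i, m in enumerate(mapped) if m is not None)
        last = len(mapped) - 1 - next(
            i for i, m in enumerate(reversed(mapped)) if m is not None
        )
        ops: list[tuple[int, int]] = []
        if first > 0:
            ops.append((4, first))  # soft clip

        def push(op: int, n: int = 1) -> None:
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))

        nm = 0
        prev_t: int | None = None
        start_t = mapped[first]
        for i in range(first, last + 1):
            t = mapped[i]
            if t is None:
                push(1)  # insertion relative to target
                nm += 1
                continue
            if prev_t is not None and t > prev_t + 1:
                gap = t - prev_t - 1
                push(2, gap)  # deletion: target bases absent from read
                nm += gap
            push(0)
            if r.query_bases[i] != target_reference[t]:
                nm += 1
            prev_t = t
        if last < len(mapped) - 1:
            ops.append((4, len(mapped) - 1 - last))
        assert start_t is not None and prev_t is not None
        out.append(
            ReadRecord(
                read_id=r.read_id,
                reference_label=target_label,
                start=start_t,
                end=prev_t + 1,
                strand=r.strand,
                mapq=r.mapq,
                cigar=tuple(ops),
                query_bases=r.query_bases,
                base_quals=r.base_quals,
                nm=nm,
            )
        )
    return out, dropped


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    """Write truth reads as standard 4-line FASTQ records."""
    with Path(path).open("w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_reference_fasta(name: str, sequence: str, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
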