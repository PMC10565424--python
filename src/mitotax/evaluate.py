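"""Coverage-sweep evaluation of the classifier on simulated samples.

For each coverage level and each source species, ``run_sweep`` simulates
replicate ancient read sets, projects them onto both references, runs the
full filter/assign/decide pipeline, and tallies verdicts into

* true positives — verdict matches the source species,
* false positives — verdict is the *other* species,
* false negatives — ``unidentified`` (counts assigned but test not
  significant),
* not evaluable — no read overlapped a target site (kept out of the
  metric denominators and reported separately).

Precision, recall and accuracy follow the three-category convention with
no true-negative class: precision = TP/(TP+FP), recall = TP/(TP+FN),
accuracy = TP/(TP+FP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .decide import VERDICT_NO_DATA, VERDICT_UNIDENTIFIED
from .bamfilter import FilterConfig
from .pipeline import classify_read_sets
from .refsites import SP1, SP2, CoordinateMap, ReferencePair, SiteSet, align_references, coordinate_map
from .simulate import SimConfig, simulate_reads, project_reads


@dataclass(frozen=True)
class PerfMetrics:
    """Precision / recall / accuracy over evaluable trials."""

    tp: int
    fp: int
    fn: int
    n_not_evaluable: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        d = self.n_evaluable
        return self.tp / d if d else float("nan")


def compute_metrics(tp: int, fp: int, fn: int, n_not_evaluable: int = 0) -> PerfMetrics:
    return PerfMetrics(tp=tp, fp=fp, fn=fn, n_not_evaluable=n_not_evaluable)


def trial_seed(master_seed: int, coverage_index: int, species_index: int, replicate: int) -> int:
    """Deterministic per-trial seed so any single trial can be re-run alone."""
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(coverage_index, species_index, replicate),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_trial(
    pair: ReferencePair,
    sites: SiteSet,
    cmap: CoordinateMap,
    source_species: str,
    coverage: float,
    seed: int,
    cfg_template: SimConfig | None = None,
    mode: str = "all",
    filters: FilterConfig | None = None,
) -> str:
    """Simulate one sample and classify it; returns the verdict string."""
    cfg_template = cfg_template or SimConfig()
    cfg = replace(
        cfg_template,
        source_species=source_species,
        target_coverage=coverage,
        seed=seed,
    )
    source_seq = pair.seq_sp1 if source_species == SP1 else pair.seq_sp2
    other = SP2 if source_species == SP1 else SP1
    other_seq = pair.seq_sp2 if source_species == SP1 else pair.seq_sp1
    _, records = simulate_reads(source_seq, cfg)
    projected, _ = project_reads(records, cmap, other_seq, other)
    reads_sp1 = records if source_species == SP1 else projected
    reads_sp2 = projected if source_species == SP1 else records
    outcome = classify_read_sets(
        reads_sp1, reads_sp2, sites, mode=mode, filters=filters
    )
    return outcome.result.verdict


def run_sweep(
    pair: ReferencePair,
    sites: SiteSet,
    coverages: Sequence[float],
    n_per_species: int,
    cfg_template: SimConfig | None = None,
    seed: int = 0,
    mode: str = "all",
    filters: FilterConfig | None = None,
    cmap: CoordinateMap | None = None,
) -> pd.DataFrame:
    """Classify simulated replicates of both species at each coverage.

    Returns one row per (coverage, source species) with verdict tallies,
    plus pooled precision/recall/accuracy per coverage (both species
    combined, mirroring how such sweeps are usually summarised).
    """
    if cmap is None:
        cmap = coordinate_map(align_references(pair))
    rows = []
    for ci, cov in enumerate(coverages):
        pooled = {"tp": 0, "fp": 0, "fn": 0, "ne": 0}
        for si, species in enumerate((SP1, SP2)):
            tally = {"correct": 0, "wrong": 0, "unidentified": 0, "no_reads": 0}
            for rep in range(n_per_species):
                verdict = run_trial(
                    pair,
                    sites,
                    cmap,
                    species,
                    cov,
                    trial_seed(seed, ci, si, rep),
                    cfg_template,
                    mode=mode,
                    filters=filters,
                )
                if verdict == species:
                    tally["correct"] += 1
                elif verdict in (VERDICT_UNIDENTIFIED,):
                    tally["unidentified"] += 1
                elif verdict == VERDICT_NO_DATA:
                    tally["no_reads"] += 1
                else:
                    tally["wrong"] += 1
            pooled["tp"] += tally["correct"]
            pooled["fp"] += tally["wrong"]
            pooled["fn"] += tally["unidentified"]
            pooled["ne"] += tally["no_reads"]
            rows.append(
                {
                    "coverage": cov,
                    "species": species,
                    "n": n_per_species,
                    **tally,
                }
            )
        metrics = compute_metrics(
            pooled["tp"], pooled["fp"], pooled["fn"], pooled["ne"]
        )
        for row in rows[-2:]:
            row["precision"] = metrics.precision
            row["recall"] = metrics.recall
            row["accuracy"] = metrics.accuracy
    return pd.DataFrame(rows)


def sweep_metrics(sweep: pd.DataFrame) -> pd.DataFrame:
    """Pooled per-coverage metrics table from a :func:`run_sweep` result."""
    grouped = sweep.groupby("coverage", sort=True)
    out = grouped[["correct", "wrong", "unidentified", "no_reads"]].sum()
    out = out.rename(
        columns={"correct": "tp", "wrong": "fp", "unidentified": "fn",
                 "no_reads": "not_evaluable"}
    )
    out["precision"] = out.tp / (out.tp + out.fp)
    out["recall"] = out.tp / (out.tp + out.fn)
    out["accuracy"] = out.tp / (out.tp + out.fp + out.fn)
    return out.reset_index()
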