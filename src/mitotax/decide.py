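"""Taxon call from SP1/SP2 read counts via an exact binomial test.

Under the null hypothesis that a read is equally likely to be labelled
either species (p0 = 0.5), the number of SP1-labelled reads among all
assigned reads is Binomial(n, 0.5).  A two-sided exact test rejects when
the split is too lopsided to be chance; the verdict is then the majority
species.  A one-tailed variant is provided for benchmarking against
samples of known identity, where the expected direction is known a priori.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

from scipy.stats import binomtest

VERDICT_UNIDENTIFIED = "unidentified"
VERDICT_NO_DATA = "no_data"

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ClassificationResult:
    """One sample's verdict with the counts and p-value behind it."""

    n_sp1: int
    n_sp2: int
    n_inconsistent: int
    p_value: float
    verdict: str
    alpha: float = DEFAULT_ALPHA
    mode: str = "all"
    site_type: int = 1

    @property
    def n_total_assigned(self) -> int:
        return self.n_sp1 + self.n_sp2


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method).

    Sums P(X = i) over all outcomes no more likely than the observed one;
    for p0 = 0.5 this reduces to twice the smaller tail, capped at 1.
    """
    if n <= 0:
        raise ValueError("two-sided test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def binom_one_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Upper-tail exact binomial p-value, P(X >= k)."""
    if n <= 0:
        raise ValueError("one-sided test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    return float(binomtest(k, n, p0, alternative="greater").pvalue)


def classify_sample(
    n_sp1: int,
    n_sp2: int,
    alpha: float = DEFAULT_ALPHA,
    n_inconsistent: int = 0,
    mode: str = "all",
    site_type: int = 1,
) -> ClassificationResult:
    """Turn read counts into a verdict.

    The verdict is a species only when that species holds the strict
    majority *and* the two-sided p-value is below ``alpha``; otherwise
    ``unidentified`` (or ``no_data`` when no read could be assigned).
    """
    if n_sp1 < 0 or n_sp2 < 0:
        raise ValueError("counts must be non-negative")
    n = n_sp1 + n_sp2
    if n == 0:
        return ClassificationResult(
            n_sp1=0,
            n_sp2=0,
            n_inconsistent=n_inconsistent,
            p_value=float("nan"),
            verdict=VERDICT_NO_DATA,
            alpha=alpha,
            mode=mode,
            site_type=site_type,
        )
    p = binom_two_sided(n_sp1, n)
    if p < alpha and n_sp1 > n_sp2:
        verdict = "SP1"
    elif p < alpha and n_sp2 > n_sp1:
        verdict = "SP2"
    else:
        verdict = VERDICT_UNIDENTIFIED
    return ClassificationResult(
        n_sp1=n_sp1,
        n_sp2=n_sp2,
        n_inconsistent=n_inconsistent,
        p_value=p,
        verdict=verdict,
        alpha=alpha,
        mode=mode,
        site_type=site_type,
    )


_REPORT_COLUMNS = (
    "sample",
    "sp1",
    "sp2",
    "coverage",
    "n_total_assigned",
    "n_sp1",
    "n_sp2",
    "n_inconsistent",
    "p_value",
    "verdict",
    "alpha",
    "mode",
    "site_type",
)


def write_report(
    result: ClassificationResult,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a per-sample report as JSON, plus a TSV row alongside it.

    ``<path>`` gets the JSON record; ``<path with .tsv suffix>`` gets a
    two-line header+row table with the classical report columns (sample,
    species labels, coverage, assigned read counts, p-value, verdict).
    Missing metadata fields default to ``"NA"``.
    """
    metadata = dict(metadata or {})
    record: dict[str, object] = {"schema_version": 1}
    record.update(asdict(result))
    record["n_total_assigned"] = result.n_total_assigned
    for key in ("sample", "sp1", "sp2", "coverage"):
        record.setdefault(key, metadata.get(key, "NA"))
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, allow_nan=True) + "\n")
    tsv = path.with_suffix(".tsv")
    row = [str(record.get(c, "NA")) for c in _REPORT_COLUMNS]
    tsv.write_text(
        "\t".join(_REPORT_COLUMNS) + "\n" + "\t".join(row) + "\n"
    )


def read_report(path: str | Path) -> tuple[ClassificationResult, dict[str, object]]:
    """Parse a JSON report back into a result plus its metadata."""
    record = json.loads(Path(path).read_text())
    result = ClassificationResult(
        n_sp1=record["n_sp1"],
        n_sp2=record["n_sp2"],
        n_inconsistent=record["n_inconsistent"],
        p_value=record["p_value"],
        verdict=record["verdict"],
        alpha=record["alpha"],
        mode=record["mode"],
        site_type=record["site_type"],
    )
    meta = {
        k: v
        for k, v in record.items()
        if k in ("sample", "sp1", "sp2", "coverage")
    }
    return result, meta
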