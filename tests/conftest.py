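"""Shared fixtures: small planted reference pairs and read builders."""

import pytest

from mitotax.bamfilter import ReadRecord
from mitotax.refsites import SP1, build_site_set, align_references, coordinate_map
from mitotax.simulate import make_reference_pair


def mk_read(
    read_id="r1",
    reference_label=SP1,
    start=0,
    seq="ACGTACGTACGT",
    strand="+",
    mapq=37,
    quals=None,
    nm=0,
    cigar=None,
):
    """Build a simple all-match ReadRecord for toy scenarios."""
    cigar = cigar or ((0, len(seq)),)
    return ReadRecord(
        read_id=read_id,
        reference_label=reference_label,
        start=start,
        end=start + sum(n for op, n in cigar if op in (0, 2, 3, 7, 8)),
        strand=strand,
        mapq=mapq,
        cigar=cigar,
        query_bases=seq,
        base_quals=tuple(quals) if quals is not None else (30,) * len(seq),
        nm=nm,
    )


@pytest.fixture(scope="session")
def small_pair():
    """2 kb pair with 10 planted transversions, 5 transitions, no indels."""
    pair, truth = make_reference_pair(
        2000, n_transversions=10, n_transitions=5, n_indels=0, seed=11
    )
    return pair, truth


@pytest.fixture(scope="session")
def indel_pair():
    """1.5 kb pair that also carries 4 short planted indels."""
    pair, truth = make_reference_pair(
        1500, n_transversions=8, n_transitions=6, n_indels=4, seed=23
    )
    return pair, truth


@pytest.fixture(scope="session")
def small_sites(small_pair):
    pair, _ = small_pair
    return build_site_set(pair)


@pytest.fixture(scope="session")
def small_cmap(small_pair):
    pair, _ = small_pair
    return coordinate_map(align_references(pair))
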