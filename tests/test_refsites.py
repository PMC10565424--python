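"""Target-site derivation: alignment, substitution extraction, filtering."""

import itertools
import shutil
import subprocess
import textwrap

import pytest

from mitotax.refsites import (
    CoordinateMap,
    PairwiseAlignment,
    ReferencePair,
    ScoringParams,
    SiteFileError,
    SiteSet,
    TargetSite,
    align_references,
    build_site_set,
    classify_substitution,
    coordinate_map,
    extract_substitutions,
    filter_polymorphic,
    find_polymorphic_positions,
    read_site_set,
    write_site_set,
)
from mitotax.simulate import make_reference_pair


class TestClassifySubstitution:
    def test_exhaustive_truth_table(self):
        """All 12 ordered unequal pairs: 4 transitions, 8 transversions."""
        results = [
            classify_substitution(a, b)
            for a, b in itertools.permutations("ACGT", 2)
        ]
        assert results.count("transition") == 4
        assert results.count("transversion") == 8
        # the transitions are exactly the within-purine/within-pyrimidine pairs
        for a, b in [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]:
            assert classify_substitution(a, b) == "transition"

    @pytest.mark.parametrize("a,b", [("A", "A"), ("A", "N"), ("X", "C")])
    def test_rejects_equal_or_non_acgt(self, a, b):
        with pytest.raises(ValueError):
            classify_substitution(a, b)


class TestAlignReferences:
    def test_identical_sequences_align_without_gaps(self):
        seq = "ACGT" * 400
        pair = ReferencePair("a", "b", seq, seq)
        aln = align_references(pair)
        assert aln.gapped_sp1 == aln.gapped_sp2 == seq
        assert extract_substitutions(aln) == []

    def test_single_deletion_yields_one_gap_run(self):
        seq = ("ACGTTGCATTAGCCAGTACG" * 5)
        deleted = seq[:40] + seq[43:]
        pair = ReferencePair("a", "b", seq, deleted)
        aln = align_references(pair)
        runs = [len(r) for r in "".join(
            c if c == "-" else " " for c in aln.gapped_sp2
        ).split()]
        assert runs == [3]
        assert aln.gapped_sp1.count("-") == 0

    def test_row_degapping_recovers_inputs(self, indel_pair):
        pair, _ = indel_pair
        aln = align_references(pair)
        assert aln.seq_sp1 == pair.seq_sp1
        assert aln.seq_sp2 == pair.seq_sp2

    def test_refuses_oversized_reference(self):
        pair = ReferencePair("a", "b", "ACGT" * 10, "ACGT" * 10)
        with pytest.raises(ValueError, match="bound"):
            align_references(pair, max_length=20)

    def test_deterministic(self, small_pair):
        pair, _ = small_pair
        a1 = align_references(pair)
        a2 = align_references(pair)
        assert a1 == a2

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_independent_aligner(self, tmp_path, indel_pair):
        """Score and substitution count agree with an independent
        global affine-gap implementation (Biostrings) under identical
        scoring."""
        pair, _ = indel_pair
        aln = align_references(pair)
        subs = extract_substitutions(aln)
        (tmp_path / "a.txt").write_text(pair.seq_sp1)
        (tmp_path / "b.txt").write_text(pair.seq_sp2)
        script = textwrap.dedent("""
            suppressMessages(library(Biostrings))
            a <- readChar("a.txt", file.info("a.txt")$size)
            b <- readChar("b.txt", file.info("b.txt")$size)
            mat <- nucleotideSubstitutionMatrix(match=1, mismatch=-2, baseOnly=TRUE)
            aln <- pairwiseAlignment(DNAString(a), DNAString(b),
                                     substitutionMatrix=mat,
                                     gapOpening=10, gapExtension=4, type="global")
            cat(score(aln), nmismatch(aln), "\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path,
            capture_output=True, text=True, check=True,
        )
        r_score, r_nmis = out.stdout.split()
        assert float(r_score) == aln.score
        assert int(r_nmis) == len(subs)


class TestExtractSubstitutions:
    def test_planted_sites_recovered_exactly(self, small_pair):
        """With planted edits and no indels, extraction returns exactly
        the planted positions, alleles and classes."""
        pair, truth = small_pair
        aln = align_references(pair)
        subs = extract_substitutions(aln)
        assert subs == truth

    def test_planted_recovery_with_indels(self, indel_pair):
        pair, truth = indel_pair
        subs = extract_substitutions(align_references(pair))
        assert subs == truth

    def test_ambiguous_column_yields_no_site(self):
        aln = PairwiseAlignment("ANCA", "ATGA", 0.0, ScoringParams())
        subs = extract_substitutions(aln)
        assert [(s.pos_sp1, s.allele_sp1, s.allele_sp2) for s in subs] == [
            (2, "C", "G")
        ]

    def test_positions_index_their_references(self, indel_pair):
        pair, _ = indel_pair
        for s in extract_substitutions(align_references(pair)):
            assert pair.seq_sp1[s.pos_sp1] == s.allele_sp1
            assert pair.seq_sp2[s.pos_sp2] == s.allele_sp2


class TestBuildSiteSet:
    def test_transversion_filter_and_provenance(self, small_pair, small_sites):
        _, truth = small_pair
        n_tv = sum(1 for t in truth if t.subst_class == "transversion")
        assert len(small_sites) == n_tv == 10
        assert small_sites.provenance["n_substitutions"] == 15
        assert small_sites.site_type == 1

    def test_identical_references_give_empty_set(self):
        seq = "ACGTTGCA" * 100
        pair = ReferencePair("a", "b", seq, seq)
        assert len(build_site_set(pair)) == 0


class TestPolymorphismFilter:
    def test_identical_panel_has_no_polymorphism(self):
        ref = "ACGTACGTAC"
        assert find_polymorphic_positions([ref, ref, ref], 10) == set()

    def test_single_variant_position_found(self):
        seqs = ["ACGTACGTAC", "ACGTACGAAC", "ACGTACGTAC"]
        assert find_polymorphic_positions(seqs, 10) == {7}

    def test_missing_data_is_not_a_second_allele(self):
        seqs = ["ACGTACGTAC", "ACGTACG-AC", "ACGTACGNAC"]
        assert find_polymorphic_positions(seqs, 10) == set()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            find_polymorphic_positions(["ACGT"], 5)

    def test_type2_is_subset_with_flags(self, small_sites):
        poly1 = {s.pos_sp1 for s in list(small_sites)[:2]}
        poly2 = {list(small_sites)[4].pos_sp2}
        type2 = filter_polymorphic(small_sites, poly1, poly2)
        assert type2.site_type == 2
        assert len(type2) + len(type2.removed) == len(small_sites)
        assert len(type2) == len(small_sites) - 3
        kept = {(s.pos_sp1, s.pos_sp2) for s in type2}
        assert kept <= {(s.pos_sp1, s.pos_sp2) for s in small_sites}
        assert all(s.polymorphic_sp1 or s.polymorphic_sp2 for s in type2.removed)

    def test_empty_filter_keeps_everything(self, small_sites):
        type2 = filter_polymorphic(small_sites, set(), set())
        assert [
            (s.pos_sp1, s.pos_sp2, s.allele_sp1, s.allele_sp2) for s in type2
        ] == [
            (s.pos_sp1, s.pos_sp2, s.allele_sp1, s.allele_sp2)
            for s in small_sites
        ]
        assert type2.site_type == 2 and not type2.removed


class TestCoordinateMap:
    def test_gapfree_alignment_gives_identity(self, small_pair):
        pair, _ = small_pair
        cmap = coordinate_map(align_references(pair))
        assert all(cmap.to_sp2(i) == i for i in range(0, 2000, 97))

    def test_known_deletion_shift(self):
        # 3 bases of sp1 (columns 7-9) are absent from sp2
        aln = PairwiseAlignment("AAACCCGGGTTTACGT",
                                "AAACCCG---TACGTA", 0.0, ScoringParams())
        cmap = coordinate_map(aln)
        assert cmap.to_sp2(13) == 10
        assert cmap.to_sp2(8) is None

    def test_round_trip_identity(self, indel_pair):
        pair, _ = indel_pair
        cmap = coordinate_map(align_references(pair))
        for p, q in cmap.map_1to2.items():
            assert cmap.to_sp1(q) == p
        pos2 = sorted(cmap.map_1to2.values())
        assert pos2 == [cmap.map_1to2[k] for k in sorted(cmap.map_1to2)]


class TestSiteSetIO:
    def test_round_trip(self, tmp_path, small_sites):
        path = tmp_path / "sites.tsv"
        write_site_set(small_sites, path)
        back = read_site_set(path)
        assert back.sites == small_sites.sites
        assert back.site_type == small_sites.site_type
        assert back.id_sp1 == small_sites.id_sp1

    def test_positions_are_one_based_on_disk(self, tmp_path, small_sites):
        path = tmp_path / "sites.tsv"
        write_site_set(small_sites, path)
        first_data = next(
            l for l in path.read_text().splitlines() if not l.startswith("#")
        )
        assert int(first_data.split("\t")[0]) == small_sites.sites[0].pos_sp1 + 1

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\tA\t1\tC\ttransversion\t0\t0\nxx\tA\t2\tC\ttransversion\t0\t0\n")
        with pytest.raises(SiteFileError, match=":2"):
            read_site_set(path)


class TestReferencePairValidation:
    def test_rejects_empty_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            ReferencePair("a", "b", "", "ACGT")
        with pytest.raises(ValueError, match="non-IUPAC"):
            ReferencePair("a", "b", "ACGZ", "ACGT")
        with pytest.raises(ValueError, match="distinct"):
            ReferencePair("a", "a", "ACGT", "ACGT")
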