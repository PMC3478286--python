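"""Input parsing, fragment extraction, the exclusion rule and balanced sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phoskit as pk
from phoskit.dataset import (
    ParseError,
    ValidationError,
    read_fragments,
    rebuild_replicate,
    window_is_standard,
    write_fragments,
)


class TestReadFasta:
    def test_single_record(self, fasta_file):
        records = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        assert len(records) == 1
        assert records[0].id == "p1" and records[0].sequence == "MKSA"

    def test_lowercase_uppercased_and_id_is_first_token(self, fasta_file):
        path = fasta_file(">p1 some description\nmksa\n>p2\nGGTY\n")
        records = pk.read_fasta(path)
        assert [r.id for r in records] == ["p1", "p2"]
        assert records[0].sequence == "MKSA"

    def test_digits_rejected(self, fasta_file):
        with pytest.raises(ParseError, match="p1"):
            pk.read_fasta(fasta_file(">p1\nMK5A\n"))

    def test_empty_file_rejected(self, fasta_file):
        with pytest.raises(ParseError):
            pk.read_fasta(fasta_file(""))

    def test_ambiguity_letters_accepted(self, fasta_file):
        records = pk.read_fasta(fasta_file(">p1\nMXSA\n"))
        assert records[0].sequence == "MXSA"

    def test_roundtrip_via_writer(self, tmp_path):
        prots = [pk.ProteinRecord("a", "MKSA" * 40), pk.ProteinRecord("b", "GGSYT")]
        path = tmp_path / "out.fasta"
        pk.write_fasta(prots, path)
        back = pk.read_fasta(path)
        assert [(p.id, p.sequence) for p in back] == [
            (p.id, p.sequence) for p in prots
        ]


class TestSiteAnnotations:
    def test_attach_site(self, fasta_file, tsv_file):
        prots = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        table = tsv_file("protein_id\tposition\tresidue\np1\t3\tS\n")
        annotated = pk.read_site_annotations(table, prots)
        assert annotated[0].sites == frozenset({3})

    def test_residue_mismatch_names_the_row(self, fasta_file, tsv_file):
        prots = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        table = tsv_file("protein_id\tposition\tresidue\np1\t3\tT\n")
        with pytest.raises(ValidationError, match=r"p1.*3.*'T'.*'S'"):
            pk.read_site_annotations(table, prots)

    def test_duplicate_rows_collapse_with_warning(self, fasta_file, tsv_file, caplog):
        prots = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        table = tsv_file(
            "protein_id\tposition\tresidue\np1\t3\tS\np1\t3\tS\n"
        )
        with caplog.at_level("WARNING"):
            annotated = pk.read_site_annotations(table, prots)
        assert annotated[0].sites == frozenset({3})
        assert "duplicate" in caplog.text

    def test_unknown_protein_rejected(self, fasta_file, tsv_file):
        prots = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        table = tsv_file("protein_id\tposition\tresidue\nzz\t3\tS\n")
        with pytest.raises(ValidationError, match="unknown protein"):
            pk.read_site_annotations(table, prots)

    def test_position_out_of_range_rejected(self, fasta_file, tsv_file):
        prots = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        table = tsv_file("protein_id\tposition\tresidue\np1\t9\tS\n")
        with pytest.raises(ValidationError, match="out of range"):
            pk.read_site_annotations(table, prots)

    def test_comment_lines_skipped(self, fasta_file, tsv_file):
        prots = pk.read_fasta(fasta_file(">p1\nMKSA\n"))
        table = tsv_file(
            "protein_id\tposition\tresidue\n# a comment\np1\t3\tS\n"
        )
        assert pk.read_site_annotations(table, prots)[0].sites == {3}


class TestExtractFragment:
    def test_left_edge_pads_with_o(self):
        prot = pk.ProteinRecord("p", "S" + "A" * 29)
        frag = pk.extract_fragment(prot, 1, n=13)
        assert frag.window == "O" * 13 + "S" + "A" * 13
        assert len(frag.window) == 27

    def test_interior_site_has_no_padding(self):
        seq = "ACDEFGHIKLMNPQSACDEFGHIKLMNPQRACDEFGHIKL"
        prot = pk.ProteinRecord("p", seq)
        frag = pk.extract_fragment(prot, 15, n=13)
        assert frag.window == seq[1:28]
        assert "O" not in frag.window

    def test_right_edge_pads_with_o(self):
        prot = pk.ProteinRecord("p", "A" * 29 + "T")
        frag = pk.extract_fragment(prot, 30, n=13)
        assert frag.window == "A" * 13 + "T" + "O" * 13

    def test_non_acceptor_center_rejected(self):
        prot = pk.ProteinRecord("p", "MKSA")
        with pytest.raises(ValidationError, match="not S/T/Y"):
            pk.extract_fragment(prot, 1, n=2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(data=st.data())
    def test_non_padding_count_matches_overlap(self, data):
        L = data.draw(st.integers(min_value=1, max_value=60))
        pos = data.draw(st.integers(min_value=1, max_value=L))
        n = data.draw(st.integers(min_value=1, max_value=20))
        seq = "A" * (pos - 1) + "S" + "A" * (L - pos)
        frag = pk.extract_fragment(pk.ProteinRecord("p", seq), pos, n=n)
        expected = min(pos + n, L) - max(pos - n, 1) + 1
        assert sum(c != "O" for c in frag.window) == expected
        assert len(frag.window) == 2 * n + 1


class TestSelectNegatives:
    def test_far_site_is_eligible(self):
        seq = "A" * 29 + "S" + "A" * 69 + "S" + "A" * 20
        prot = pk.ProteinRecord("p", seq, sites=frozenset({100}))
        assert 30 in pk.select_negative_positions(prot, "S", d=50)

    def test_near_site_is_excluded(self):
        seq = "A" * 59 + "S" + "A" * 39 + "S" + "A" * 20
        prot = pk.ProteinRecord("p", seq, sites=frozenset({100}))
        assert 60 not in pk.select_negative_positions(prot, "S", d=50)

    def test_boundary_is_strict(self):
        # |p - s| == d is still excluded; eligibility needs |p - s| > d
        seq = "A" * 49 + "S" + "A" * 49 + "S" + "A" * 60
        prot = pk.ProteinRecord("p", seq, sites=frozenset({100}))
        eligible = pk.select_negative_positions(prot, "S", d=50)
        assert 50 not in eligible
        assert 50 in pk.select_negative_positions(prot, "S", d=49)

    def test_no_sites_returns_all_of_type(self):
        prot = pk.ProteinRecord("p", "ASASAT")
        assert pk.select_negative_positions(prot, "S", d=50) == [2, 4]

    def test_exclusion_counts_sites_of_other_types(self):
        # an annotated T site also vetoes nearby S negatives
        seq = "S" + "A" * 29 + "T" + "A" * 69
        prot = pk.ProteinRecord("p", seq, sites=frozenset({31}))
        assert 1 not in pk.select_negative_positions(prot, "S", d=50)

    def test_output_disjoint_from_sites(self, sim_proteome):
        proteins, _ = sim_proteome
        for prot in proteins[:10]:
            eligible = set(pk.select_negative_positions(prot, "S"))
            assert eligible.isdisjoint(prot.sites)


class TestBalancedSets:
    def test_counts_and_shared_positives(self, balanced_sets):
        assert len(balanced_sets) == 3
        first = balanced_sets[0]
        assert len(first.positives) == len(first.negatives)
        for bset in balanced_sets[1:]:
            assert bset.positives == first.positives

    def test_same_seed_reproduces_draws(self, sim_proteome):
        proteins, _ = sim_proteome
        a = pk.build_balanced_sets(proteins, "S", replicates=2, seed=5)
        b = pk.build_balanced_sets(proteins, "S", replicates=2, seed=5)
        assert a == b

    def test_replicates_differ_with_large_pool(self, balanced_sets):
        negs = [bset.negatives for bset in balanced_sets]
        assert len(set(negs)) > 1

    def test_recorded_seed_rebuilds_replicate(self, sim_proteome, balanced_sets):
        proteins, _ = sim_proteome
        target = balanced_sets[1]
        rebuilt = rebuild_replicate(
            proteins, "S", target.seed, replicate_index=target.replicate_index
        )
        assert rebuilt == target

    def test_infeasible_balance_reports_counts(self):
        # single protein: every S within 50 of the annotated site
        prot = pk.ProteinRecord("p", "SASAS" + "A" * 30, sites=frozenset({1}))
        with pytest.raises(ValidationError, match="pool"):
            pk.build_balanced_sets([prot], "S", replicates=2, seed=0)

    def test_ambiguous_windows_dropped(self, caplog):
        seq = "A" * 18 + "X" + "A" * 12 + "S" + "A" * 80 + "S" + "A" * 30
        prot = pk.ProteinRecord("p", seq, sites=frozenset({32}))  # X at 19 is in-window
        with caplog.at_level("WARNING"):
            sets = pk.build_balanced_sets([prot], "S", replicates=1, seed=0)
        # the positive at 32 has X in its window and is dropped
        assert len(sets[0].positives) == 0
        assert "dropping positive" in caplog.text


class TestFragmentIO:
    def test_roundtrip(self, tmp_path, balanced_sets):
        frags = balanced_sets[0].fragments
        path = tmp_path / "frags.tsv"
        write_fragments(frags, path)
        assert read_fragments(path) == frags

    def test_window_invariant_enforced(self):
        with pytest.raises(ValidationError, match="padding"):
            pk.SiteFragment("p", 5, "S", "AOSOA", label="positive")
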