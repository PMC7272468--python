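"""Polymorphic-site discovery from aligned promoter panels."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promvar.alignment import (
    AlignmentError,
    AlignmentRecord,
    PromoterAlignment,
    call_polymorphic_sites,
    column_to_coordinate,
    read_aligned_fasta,
    read_site_table,
    write_aligned_fasta,
    write_site_table,
)


def brute_force_sites(aln):
    """Independent per-column scanner that merges adjacent gap columns.

    Returns {(coordinate, kind): {acc: allele}} for comparison with the
    implementation; missing encoded as None.
    """
    seqs = {r.accession_id: r.sequence for r in aln.records}
    ref = seqs[aln.reference_id]
    out = {}
    cols = list(range(aln.atg_column))
    is_gap = [any(seqs[a][c] == "-" for a in seqs) for c in cols]
    c = 0
    while c < aln.atg_column:
        if is_gap[c]:
            start = c
            while c < aln.atg_column and is_gap[c]:
                c += 1
            calls = {}
            for a in seqs:
                seg = seqs[a][start:c]
                calls[a] = None if "N" in seg else seg.replace("-", "")
            if len({v for v in calls.values() if v is not None}) >= 2:
                coord = -sum(1 for x in ref[start : aln.atg_column] if x != "-")
                out[(coord, "indel")] = calls
        else:
            calls = {a: (None if seqs[a][c] == "N" else seqs[a][c]) for a in seqs}
            if len({v for v in calls.values() if v is not None}) >= 2:
                coord = -sum(1 for x in ref[c : aln.atg_column] if x != "-")
                out[(coord, "SNP")] = calls
            c += 1
    return out


class TestReadWrite:
    def test_fasta_round_trip_uppercases(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a subgroup=indica\nacgt\n>b subgroup=aus\nACGA\n")
        aln = read_aligned_fasta(path, "a", 4)
        assert [r.sequence for r in aln.records] == ["ACGT", "ACGA"]
        out = tmp_path / "roundtrip.fasta"
        write_aligned_fasta(aln, out)
        again = read_aligned_fasta(out, "a", 4)
        assert [(r.accession_id, r.subgroup, r.sequence) for r in again.records] == [
            ("a", "indica", "ACGT"),
            ("b", "aus", "ACGA"),
        ]

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentError, match="ragged"):
            read_aligned_fasta(path, "a", 3)

    def test_missing_reference_rejected(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nACGT\n>b\nACGA\n")
        with pytest.raises(AlignmentError, match="reference"):
            read_aligned_fasta(path, "nope", 4)

    def test_non_alphabet_character_rejected(self):
        with pytest.raises(AlignmentError, match="non-alphabet"):
            AlignmentRecord("a", "other", "ACXT")


class TestCoordinates:
    def test_column_immediately_before_atg(self, toy_alignment):
        assert column_to_coordinate(toy_alignment, 8) == -1

    def test_reference_gaps_not_counted(self):
        # reference gapped at 3 of the 10 columns upstream of column 10
        ref = "AC--A-CGTTATG"
        other = "ACGTATCGTTATG"
        aln = PromoterAlignment(
            [AlignmentRecord("R", "other", ref), AlignmentRecord("S", "other", other)],
            "R",
            10,
        )
        assert column_to_coordinate(aln, 0) == -7
        # gap column anchors at the next reference base 3' of it
        assert column_to_coordinate(aln, 2) == -5

    def test_full_length_gap_free_promoter(self):
        seq = "A" * 2000 + "ATG"
        aln = PromoterAlignment(
            [AlignmentRecord("R", "other", seq), AlignmentRecord("S", "other", seq)],
            "R",
            2000,
        )
        assert column_to_coordinate(aln, 0) == -2000

    def test_column_at_or_after_atg_rejected(self, toy_alignment):
        with pytest.raises(AlignmentError):
            column_to_coordinate(toy_alignment, 9)


class TestCallSites:
    def test_identical_records_give_no_sites(self):
        seq = "ACGTACGTGATG"
        aln = PromoterAlignment(
            [AlignmentRecord(i, "other", seq) for i in "AB"], "A", 9
        )
        assert call_polymorphic_sites(aln) == []

    def test_toy_alignment_matches_brute_force(self, toy_alignment):
        sites = call_polymorphic_sites(toy_alignment)
        expected = brute_force_sites(toy_alignment)
        assert len(sites) == 2
        assert {(s.coordinate, s.kind) for s in sites} == set(expected)
        for s in sites:
            assert s.calls == expected[(s.coordinate, s.kind)]
        indel = next(s for s in sites if s.kind == "indel")
        assert indel.ref_allele == "TA" and indel.alt_alleles == [""]
        snp = next(s for s in sites if s.kind == "SNP")
        assert snp.ref_allele == "G" and snp.alt_alleles == ["T"]

    def test_sites_sorted_most_upstream_first(self, toy_alignment):
        coords = [s.coordinate for s in call_polymorphic_sites(toy_alignment)]
        assert coords == sorted(coords)

    def test_known_insertion_anchored_at_minus_1377(self):
        """An AAAAGCTC insertion whose anchor lies 1377 bases 5' of ATG."""
        promoter = ("ACGT" * 500)[:1500]
        anchor = 1500 - 1377
        japonica = promoter + "ATG"
        indica = promoter[:anchor] + "AAAAGCTC" + promoter[anchor:] + "ATG"
        jap_aligned = promoter[:anchor] + "-" * 8 + promoter[anchor:] + "ATG"
        aln = PromoterAlignment(
            [
                AlignmentRecord("JAP", "temperate_japonica", jap_aligned),
                AlignmentRecord("IND", "indica", indica),
            ],
            "JAP",
            1508,
        )
        (site,) = call_polymorphic_sites(aln)
        assert site.kind == "indel"
        assert site.coordinate == -1377
        assert site.ref_allele == ""
        assert site.alt_alleles == ["AAAAGCTC"]
        assert len(japonica) + 8 == len(indica)

    def test_n_is_missing_not_an_allele(self):
        rows = [("A", "ACG"), ("B", "ANG"), ("C", "ACG")]
        aln = PromoterAlignment(
            [AlignmentRecord(i, "other", s + "ATG") for i, s in rows], "A", 3
        )
        assert call_polymorphic_sites(aln) == []

    def test_adding_reference_identical_record_is_neutral(self, toy_alignment):
        before = call_polymorphic_sites(toy_alignment)
        extra = AlignmentRecord("DUP", "other", toy_alignment.reference_sequence)
        grown = PromoterAlignment(
            toy_alignment.records + [extra], "REF", toy_alignment.atg_column
        )
        after = call_polymorphic_sites(grown)
        assert [(s.site_id, s.coordinate, s.kind, s.ref_allele, s.alt_alleles) for s in before] == [
            (s.site_id, s.coordinate, s.kind, s.ref_allele, s.alt_alleles) for s in after
        ]

    def test_zero_promoter_columns_rejected(self):
        with pytest.raises(AlignmentError):
            PromoterAlignment([AlignmentRecord("A", "other", "ATG")], "A", 0)


@st.composite
def random_alignments(draw):
    n_records = draw(st.integers(2, 8))
    n_cols = draw(st.integers(4, 40))
    rows = []
    for i in range(n_records):
        chars = draw(
            st.lists(
                st.sampled_from("ACGTN-" if i > 0 else "ACGT"),
                min_size=n_cols,
                max_size=n_cols,
            )
        )
        rows.append(AlignmentRecord(f"R{i}", "other", "".join(chars) + "ATG"))
    return PromoterAlignment(rows, "R0", n_cols)


@given(random_alignments())
@settings(max_examples=150, deadline=None)
def test_implementation_matches_brute_force_scanner(aln):
    sites = call_polymorphic_sites(aln)
    expected = brute_force_sites(aln)
    assert {(s.coordinate, s.kind) for s in sites} == set(expected)
    for s in sites:
        assert s.calls == expected[(s.coordinate, s.kind)]


def test_site_table_round_trips_exactly(default_panel, tmp_path):
    sites = call_polymorphic_sites(default_panel.cultivated_alignment())
    path = tmp_path / "sites.tsv"
    write_site_table(sites, path)
    again = read_site_table(path)
    assert len(again) == len(sites)
    for a, b in zip(sites, again):
        assert (a.site_id, a.coordinate, a.kind, a.ref_allele, a.alt_alleles) == (
            b.site_id,
            b.coordinate,
            b.kind,
            b.ref_allele,
            b.alt_alleles,
        )
        assert a.calls == b.calls
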