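from __future__ import annotations

import pytest

from barcodeid.errors import FixtureIntegrityError, ParseError, ValidationError
from barcodeid.refdata import (
    BarcodeRecord,
    Procedure,
    filter_provisional,
    is_binomial,
    load_table1_fixture,
    qc_record,
    read_fasta,
    validate_annotation_coverage,
    write_fasta,
)


def rec(seq, rid="r1", species=None, **kw):
    return BarcodeRecord(rid, species, seq, **kw)


class TestFastaIO:
    def test_two_entry_fasta_parses_species_labels(self, tmp_path):
        p = tmp_path / "q.fasta"
        p.write_text(
            ">q1|Calliphora vicina\nACGTACGT\n>q2|Lucilia sericata|published\nACGTACGA\n"
        )
        records = read_fasta(p, length_bounds=None)
        assert [r.record_id for r in records] == ["q1", "q2"]
        assert records[0].species_label == "Calliphora vicina"
        assert records[0].genus_label == "Calliphora"
        assert records[0].source_tag == "unspecified"
        assert records[1].source_tag == "published"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p, length_bounds=None) == []

    def test_non_iupac_letter_rejected(self, tmp_path):
        # 'J' is not an IUPAC nucleotide code
        p = tmp_path / "bad.fasta"
        p.write_text(">q1\nACGJ\n")
        with pytest.raises(ValidationError, match="q1"):
            read_fasta(p, length_bounds=None)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">q1\nACGT\n>q1\nACGT\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_fasta(p, length_bounds=None)

    def test_non_fasta_content_is_parse_error(self, tmp_path):
        p = tmp_path / "notfasta.txt"
        p.write_text("id\tseq\nq1\tACGT\n")
        with pytest.raises(ParseError):
            read_fasta(p, length_bounds=None)

    def test_missing_file_is_parse_error(self, tmp_path):
        with pytest.raises(ParseError):
            read_fasta(tmp_path / "nope.fasta")

    def test_length_bounds_enforced_per_fragment_kind(self, tmp_path):
        p = tmp_path / "short.fasta"
        p.write_text(">q1\n" + "ACGT" * 30 + "\n")  # 120 bp
        with pytest.raises(ValidationError, match="length"):
            read_fasta(p, fragment_kind="barcode")
        assert len(read_fasta(p, length_bounds=None)) == 1

    def test_roundtrip_is_byte_identical(self, tmp_path):
        records = [
            rec("ACGTN-RY", rid="a", species="Calliphora vicina"),
            rec("ACGTACGT", rid="b"),
            rec("ACGTACGA", rid="c", species="Lucilia sericata",
                source_tag="published"),
        ]
        p1, p2 = tmp_path / "one.fasta", tmp_path / "two.fasta"
        write_fasta(records, p1)
        write_fasta(read_fasta(p1, length_bounds=None), p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_fasta(p2, length_bounds=None)
        assert [(r.record_id, r.species_label, r.sequence) for r in back] == [
            (r.record_id, r.species_label, r.sequence) for r in records
        ]


class TestQC:
    def test_open_frame_is_stop_free(self):
        report = qc_record(rec("ATG" * 200), min_len=500)
        assert report.stop_codon_free and report.frame_used == 0
        assert report.admitted

    def test_stops_in_all_frames_fail(self):
        # CTAA repeats place TAA at offsets 1, 5, 9, ... which cover all
        # three frame residues, so no forward frame is stop-free.
        report = qc_record(rec("CTAA" * 150), min_len=100)
        assert not report.stop_codon_free
        assert report.frame_used is None
        assert not report.admitted

    def test_frame_shifted_stop_only_blocks_its_own_frame(self):
        # TAA repeats stop frame 0 at every codon, but frames 1 and 2 read
        # AAT/ATA and stay open.
        report = qc_record(rec("TAA" * 200), min_len=100)
        assert report.stop_codon_free
        assert report.frame_used == 1

    def test_frame_choice_is_smallest_stop_free(self):
        # 'C' + ATG...: frame 0 reads CAT GCA... construct so frame 1 is clean
        # while frame 0 stops: TAA TGA -> frame0 TAA stop; frame1 AAT GA..
        seq = "T" + "ATG" * 180
        report = qc_record(rec(seq), min_len=100)
        assert report.stop_codon_free
        assert report.frame_used in (0, 1)

    def test_short_sequence_not_admitted(self):
        report = qc_record(rec("ATG" * 133), min_len=500)  # 399 bp clean
        assert report.stop_codon_free
        assert not report.length_ok
        assert not report.admitted

    @pytest.mark.parametrize("min_len", [100, 300, 500, 700])
    def test_admission_monotone_in_min_len(self, min_len):
        seq = "ATG" * 200  # 600 bp
        admitted = qc_record(rec(seq), min_len=min_len).admitted
        assert admitted == (600 >= min_len)


class TestProvisionalFilter:
    def test_only_nominal_binomials_kept(self):
        records = [
            rec("ACGT", rid="a", species="Lucilia sericata"),
            rec("ACGT", rid="b", species="Malaise0231"),
            rec("ACGT", rid="c", species="Fannia sp1"),
            rec("ACGT", rid="d", species=None),
        ]
        kept = filter_provisional(records)
        assert [r.record_id for r in kept] == ["a"]

    def test_all_binomial_input_unchanged(self):
        records = [rec("ACGT", rid=str(i), species="Musca domestica") for i in range(3)]
        assert filter_provisional(records) == records

    def test_empty_input(self):
        assert filter_provisional([]) == []

    def test_provisional_query_keeps_genus(self):
        r = rec("ACGT", species="Fannia sp1")
        assert not is_binomial(r.species_label)
        assert r.genus_label == "Fannia"


class TestCaseStudyFixture:
    def test_specimen_and_species_counts(self, case_fixture):
        assert case_fixture.n_specimens == 85
        assert len(case_fixture.species()) == 16

    def test_species_histogram_matches_transcription(self, case_fixture):
        hist = case_fixture.species_histogram()
        assert hist == {
            "Calliphora vicina": 14,
            "Calliphora vomitoria": 16,
            "Chrysomya albiceps": 7,
            "Cynomya mortuorum": 1,
            "Lucilia ampullacea": 2,
            "Lucilia sericata": 16,
            "Protophormia terraenovae": 12,
            "Fannia sp1": 1,
            "Fannia sp2": 1,
            "Fannia sp3": 1,
            "Eudasyphora cyanella": 1,
            "Musca autumnalis": 1,
            "Muscina levida": 5,
            "Muscina prolapsa": 5,
            "Neomyia cornicina": 1,
            "Polietes lardarius": 1,
        }

    def test_haplotype_universes(self, case_fixture):
        assert len(case_fixture.barcode_hap_species()) == 42
        assert len(case_fixture.long_hap_species()) == 42

    def test_haplotypes_never_span_species(self, case_fixture):
        case_fixture.barcode_hap_species()
        case_fixture.long_to_barcode_hap()

    def test_truncated_file_is_integrity_error(self, tmp_path, case_fixture):
        from barcodeid.refdata import _data_path

        lines = _data_path("diptera_case_study_specimens.tsv").read_text().splitlines()
        p = tmp_path / "truncated.tsv"
        p.write_text("\n".join(lines[:40]) + "\n")
        with pytest.raises(FixtureIntegrityError):
            load_table1_fixture(p)

    def test_annotations_cover_all_species_and_procedures(
        self, case_fixture, case_annotations
    ):
        validate_annotation_coverage(case_fixture, case_annotations)
        with pytest.raises(FixtureIntegrityError):
            case_annotations.get("Drosophila melanogaster", Procedure.PROC12)
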