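import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    CompoundLocation,
    ExactPosition,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from cubkit import InputError, RawCDS, extract_cds, filter_cds
from cubkit.cds_io import REJECTION_REASONS

from conftest import make_cds


def _genbank_file(tmp_path):
    """A synthetic GenBank record with forward, complement, join and
    partial CDS features (constructed programmatically, not copied)."""
    cds = make_cds(["GGT", "CCA"])  # clean 303-nt CDS
    genome = cds + "TTTT" + str(Seq(cds).reverse_complement()) + "AAAA" + cds
    rec = SeqRecord(Seq(genome), id="SYN00001", name="SYN00001",
                    description="synthetic test genome")
    rec.annotations["molecule_type"] = "DNA"
    n = len(cds)
    features = [
        SeqFeature(SimpleLocation(0, n, strand=1), type="CDS",
                   qualifiers={"gene": ["fwd"]}),
        SeqFeature(SimpleLocation(n + 4, 2 * n + 4, strand=-1), type="CDS",
                   qualifiers={"gene": ["rev"]}),
        # join of the two halves of the final copy (splicing check)
        SeqFeature(
            CompoundLocation([
                SimpleLocation(2 * n + 8, 2 * n + 8 + 150, strand=1),
                SimpleLocation(2 * n + 8 + 150, 3 * n + 8, strand=1),
            ]),
            type="CDS", qualifiers={"gene": ["joined"]},
        ),
        SeqFeature(
            SimpleLocation(ExactPosition(0), AfterPosition(n), strand=1),
            type="CDS", qualifiers={"gene": ["trailing_partial"]},
        ),
    ]
    rec.features = features
    path = tmp_path / "synthetic.gb"
    seqio_write([rec], str(path), "genbank")
    return str(path), cds


def test_genbank_extraction_strand_join_partial(tmp_path):
    path, cds = _genbank_file(tmp_path)
    raw = extract_cds(path, "SYN00001")
    by_name = {r.source_id.rsplit("_", 1)[0]: r for r in raw}
    assert by_name["fwd"].seq == cds
    assert by_name["rev"].seq == cds  # reverse complement undone
    assert by_name["joined"].seq == cds  # exons concatenated
    assert by_name["trailing_partial"].partial
    assert not by_name["fwd"].partial


def test_fasta_extraction_counts(tmp_path):
    p = tmp_path / "three.fasta"
    p.write_text(">a\nATGAAATAA\n>b\nATGCCCTAA\n>c\nATGGGGTAA\n")
    raw = extract_cds(str(p), "x")
    assert len(raw) == 3
    assert all(not r.partial for r in raw)


def test_empty_input_rejected(tmp_path):
    p = tmp_path / "nothing.fasta"
    p.write_text("")
    with pytest.raises(InputError):
        extract_cds(str(p), "x")


@pytest.mark.parametrize(
    "seq,reason",
    [
        ("ATGAAATAA", "short"),
        (make_cds(["TGA"]), "internal_stop"),
        (make_cds([])[:-3] + "AAA", "no_stop_end"),
        ("TTG" + make_cds([])[3:], "no_atg_start"),
        (make_cds([]) + "AA", "not_multiple_of_3"),
        (make_cds(["ANA"]), "ambiguous_base"),
    ],
)
def test_single_violation_rejections(space, seq, reason):
    genes, report = filter_cds([seq], space)
    assert genes == []
    assert report.rejection_tally[reason] == 1
    assert sum(report.rejection_tally.values()) == 1


def test_clean_sequence_passes(space):
    genes, report = filter_cds([make_cds(["GGT"])], space)
    assert report.n_pass == 1 and report.n_raw == 1
    g = genes[0]
    assert g.length_nt % 3 == 0 and g.length_nt >= 300
    assert g.L_aa == g.length_nt // 3 - 1
    assert sum(g.codon_counts.values()) == g.length_nt // 3
    # exactly one stop codon: the terminal one
    assert sum(g.codon_counts.get(s, 0) for s in space.stop_codons) == 1


def test_rejection_precedence_first_failure_wins(space):
    """A sequence violating several rules is tallied once, under the first
    failing check (partial > frame > length > start > ...)."""
    bad = "TTG" + "A" * 7  # partial + wrong frame + short + bad start
    genes, report = filter_cds([RawCDS(bad, "multi", partial=True)], space)
    assert report.rejection_tally["partial"] == 1
    assert sum(report.rejection_tally.values()) == 1

    genes, report = filter_cds([RawCDS(bad, "multi", partial=False)], space)
    assert report.rejection_tally["not_multiple_of_3"] == 1


def test_report_conservation_and_idempotence(space):
    seqs = [
        make_cds(["GGT"]),
        make_cds(["CCC"]),
        "ATGAAATAA",
        "TTG" + make_cds([])[3:],
        make_cds(["TAG"]),
    ]
    genes, report = filter_cds(seqs, space)
    assert report.n_pass + sum(report.rejection_tally.values()) == report.n_raw
    # Filtering what already passed changes nothing.
    genes2, report2 = filter_cds([g.sequence for g in genes], space)
    assert [g.sequence for g in genes2] == [g.sequence for g in genes]
    assert report2.n_pass == report2.n_raw == len(genes)


def test_ten_sequence_tally_fixture(space):
    """Three clean sequences pass; each violation type is tallied once."""
    fixture = [
        RawCDS(make_cds(["GGT"]), "clean1"),
        RawCDS(make_cds(["CCA"]), "clean2"),
        RawCDS(make_cds(["TCT"]), "clean3"),
        RawCDS(make_cds(["GGT"]), "part", partial=True),
        RawCDS(make_cds(["GGT"]) + "AA", "frame"),
        RawCDS("ATGAAATAA", "short"),
        RawCDS("TTG" + make_cds([])[3:], "start"),
        RawCDS(make_cds([])[:-3] + "AAA", "stopless"),
        RawCDS(make_cds(["TGA"]), "internal"),
        RawCDS(make_cds(["ANA"]), "ambig"),
    ]
    genes, report = filter_cds(fixture, space)
    assert report.n_raw == 10 and report.n_pass == 3
    assert {g.gene_id for g in genes} == {"clean1", "clean2", "clean3"}
    assert all(report.rejection_tally[r] == 1 for r in REJECTION_REASONS)
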