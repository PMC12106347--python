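"""I/O, genetic codes, telomeres and the contig filter."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliome import (
    Contig, EUPLOTES, FormatError, GeneticCode, InputError, OXYTRICHA,
    STANDARD, detect_telomeres, filter_contigs, read_edgelist, read_fasta,
    read_gff3, read_hits_tabular, reverse_complement, translate, write_fasta,
    write_gff3,
)
from ciliome.geno_io import GeneModel

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestGeneticCode:
    def test_reassignments(self):
        assert EUPLOTES["TGA"] == "C"
        assert EUPLOTES.stop_codons == ("TAA", "TAG")
        assert OXYTRICHA["TAA"] == "Q" and OXYTRICHA["TAG"] == "Q"
        assert OXYTRICHA.stop_codons == ("TGA",)
        assert len(STANDARD.table) == 64

    def test_reassigning_a_sense_codon_is_rejected(self):
        with pytest.raises(ValueError, match="not a stop"):
            GeneticCode("bad", (("ATG", "C"),))

    @pytest.mark.parametrize("seq,code,frame,expected", [
        ("TGA", EUPLOTES, 1, "C"),
        ("TAA", EUPLOTES, 1, "*"),
        ("ATGTGATAA", EUPLOTES, 1, "MC*"),
        ("ATGTGATAA", STANDARD, 1, "M**"),
        ("AATGTGA", EUPLOTES, 2, "MC"),
        ("ATGNNNTAA", EUPLOTES, 1, "MX*"),
        ("AT", EUPLOTES, 1, ""),
    ])
    def test_translate_examples(self, seq, code, frame, expected):
        assert translate(seq, code, frame) == expected

    @given(seq=dna)
    @settings(derandomize=True, max_examples=100)
    def test_euplotes_differs_from_standard_only_at_tga(self, seq):
        std = translate(seq, STANDARD)
        eup = translate(seq, EUPLOTES)
        for i, (a, b) in enumerate(zip(std, eup)):
            codon = seq[3 * i:3 * i + 3]
            if codon == "TGA":
                assert (a, b) == ("*", "C")
            else:
                assert a == b

    @given(seq=dna.filter(lambda s: len(s) >= 3))
    @settings(derandomize=True, max_examples=100)
    def test_translation_matches_ncbi_tables(self, seq):
        """Independent oracle: Biopython's NCBI tables 10 (Euplotid) and 6
        (ciliate UAR->Gln) agree with our reassignment-built codes."""
        trimmed = seq[:len(seq) - len(seq) % 3]
        assert translate(trimmed, EUPLOTES) == str(
            Seq(trimmed).translate(table=10))
        assert translate(trimmed, OXYTRICHA) == str(
            Seq(trimmed).translate(table=6))


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        assert read_fasta(p) == [("a", "ACGT")]

    def test_round_trip_random_records(self, tmp_path, rng):
        records = [(f"rec{i}", "".join(rng.choice(list("ACGTN"), size=int(n))))
                   for i, n in enumerate(rng.integers(1, 400, size=100))]
        path = write_fasta(records, tmp_path / "r.fasta")
        assert read_fasta(path) == records

    def test_lowercase_and_wrapping_normalized(self, tmp_path):
        p = tmp_path / "w.fasta"
        p.write_text(">x desc\nacg\nTtA\n")
        assert read_fasta(p) == [("x", "ACGTTA")]

    def test_empty_and_malformed(self, tmp_path):
        empty = tmp_path / "e.fasta"
        empty.write_text("")
        with pytest.raises(FormatError, match="1"):
            read_fasta(empty)
        bad = tmp_path / "b.fasta"
        bad.write_text("ACGT\n")
        with pytest.raises(FormatError, match="1"):
            read_fasta(bad)


class TestTelomeres:
    def test_both_ends_flagged(self, rng):
        gene = "".join(rng.choice(list("ACGT"), size=500))
        seq = "CCCCAAAA" * 4 + gene + "TTTTGGGG" * 4
        out = detect_telomeres(Contig("c", seq))
        assert out.telomere_5p and out.telomere_3p

    def test_random_sequence_unflagged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        out = detect_telomeres(Contig("c", seq))
        assert not out.telomere_5p and not out.telomere_3p

    def test_repeats_only(self):
        seq = "CCCCAAAA" * 3 + "TTTTGGGG" * 3
        out = detect_telomeres(Contig("c", seq))
        assert out.telomere_5p and out.telomere_3p


class TestFilterContigs:
    def test_toy_set_exact_removals(self, toy_contig_set):
        contigs, hits, expected = toy_contig_set
        kept, removed = filter_contigs(contigs, hits)
        assert {c.id: r for c, r in removed} == expected
        assert len(kept) + len(removed) == len(contigs)

    def test_idempotent(self, toy_contig_set):
        contigs, hits, _ = toy_contig_set
        kept, _ = filter_contigs(contigs, hits)
        kept_ids = {c.id for c in kept}
        hits2 = [h for h in hits
                 if h.query_id in kept_ids and h.subject_id in kept_ids]
        kept2, removed2 = filter_contigs(kept, hits2)
        assert removed2 == [] and kept2 == kept

    def test_unknown_id_rejected(self, toy_contig_set):
        contigs, _, _ = toy_contig_set
        from tests.conftest import make_hit
        with pytest.raises(InputError, match="unknown contig"):
            filter_contigs(contigs, [make_hit("ghost", "long1")])


class TestTabularFormats:
    def test_outfmt6_evalue(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t98.5\t100\t1\t0\t1\t100\t5\t104\t1e-20\t185.3\n")
        (hit,) = read_hits_tabular(p)
        assert hit.evalue == 1e-20 and hit.subject_id == "s1"

    def test_column_mismatch_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q1\ts1\t98.5\n")
        with pytest.raises(FormatError, match=":1"):
            read_hits_tabular(p)

    def test_gff3_exons_to_introns(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "ctg1\t.\tgene\t1\t900\t.\t+\t.\tID=g1\n"
            "ctg1\t.\tmRNA\t1\t900\t.\t+\t.\tID=m1;Parent=g1\n"
            "ctg1\t.\texon\t1\t300\t.\t+\t.\tParent=m1\n"
            "ctg1\t.\texon\t400\t600\t.\t+\t.\tParent=m1\n"
            "ctg1\t.\texon\t700\t900\t.\t+\t.\tParent=m1\n")
        (model,) = read_gff3(p)
        assert model.n_introns == 2 and model.gene_id == "g1"

    def test_gff3_round_trip(self, tmp_path):
        models = [GeneModel("g1", "m1", "ctg1", "+", ((1, 300), (400, 900))),
                  GeneModel("g2", "m2", "ctg2", "-", ((10, 500),))]
        path = write_gff3(models, tmp_path / "out.gff3")
        assert read_gff3(path) == models

    def test_edgelist_dedup_and_self_loop(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\nb\ta\nb\tc\n")
        g = read_edgelist(p)
        assert g.number_of_edges() == 2
        bad = tmp_path / "s.tsv"
        bad.write_text("a\ta\n")
        with pytest.raises(FormatError, match="self-loop"):
            read_edgelist(bad)


def test_reverse_complement():
    assert reverse_complement("CCCCAAAA") == "TTTTGGGG"
    assert reverse_complement("ACGTN") == "NACGT"
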