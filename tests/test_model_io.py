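"""Domain types, loaders/writers, transcript selection and motif unions."""

import string

import pytest
from hypothesis import given, settings, strategies as st

from synreg.io import (
    FormatError,
    read_bed_track,
    read_codon_table,
    read_gene_rates,
    read_mirna_fasta,
    read_motif_list,
    read_mutation_table,
    read_transcripts_bed12,
    read_transcripts_gff3,
    write_bed_track,
    write_mutation_table,
    write_mutation_vcf,
    write_transcripts_bed12,
)
from synreg.model import (
    InvariantError,
    MotifSet,
    Mutation,
    select_longest_transcript,
    union_motif_sets,
)

from conftest import make_mutation, make_transcript


TSV_HEADER = "gene\ttranscript\tchrom\tpos\tref\talt\tstrand\tscore\tsample_count\tcds_pos\tcontext\n"


def _tsv_row(ref="C", alt="T", score="0.8", nsamp="2"):
    return f"G1\tT1\tchr1\t150\t{ref}\t{alt}\t+\t{score}\t{nsamp}\t6\tAAAAA{ref}AAAAA\n"


class TestMutationTable:
    def test_well_formed_rows_round_trip(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(TSV_HEADER + _tsv_row("C", "T") + _tsv_row("G", "A") + _tsv_row("A", "G"))
        muts, rejects = read_mutation_table(path)
        assert len(muts) == 3 and rejects == []
        out = tmp_path / "roundtrip.tsv"
        write_mutation_table(muts, out)
        again, rejects2 = read_mutation_table(out)
        assert again == muts and rejects2 == []

    def test_identity_substitution_rejected_not_dropped_silently(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(TSV_HEADER + _tsv_row("C", "C"))
        muts, rejects = read_mutation_table(path)
        assert muts == [] and len(rejects) == 1
        assert "substitution" in rejects[0].reason

    def test_missing_column_is_a_format_error_naming_it(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tchrom\npos\n")
        with pytest.raises(FormatError, match="transcript"):
            read_mutation_table(path)

    def test_missing_score_loads_as_none(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(TSV_HEADER + _tsv_row(score=""))
        muts, rejects = read_mutation_table(path)
        assert len(muts) == 1 and muts[0].score is None

    def test_vcf_round_trip_matches_tsv_records(self, tmp_path):
        muts = [
            make_mutation(context="AAAAACAAAAA", ref="C", alt="T", pos=150, score=0.83),
            make_mutation(
                context="AAAAAGAAAAA", ref="G", alt="A", pos=220, cds_pos=9,
                strand="-", score=0.41, sample_count=1,
            ),
        ]
        path = tmp_path / "m.vcf"
        write_mutation_vcf(muts, path)
        # minus-strand REF in the file must be the plus-strand complement
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[1].split("\t")[3] == "C"  # revcomp of coding-strand G
        loaded, rejects = read_mutation_table(path, dialect="vcf")
        assert rejects == []
        assert sorted(loaded, key=lambda m: m.pos) == sorted(muts, key=lambda m: m.pos)

    def test_vcf_without_required_info_header_fails(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t150\t.\tC\tT\t.\t.\t.\n"
        )
        with pytest.raises(FormatError, match="GENE"):
            read_mutation_table(path, dialect="vcf")


class TestMutationInvariants:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(ref="C", alt="C", context="AAAAACAAAAA"), "substitution"),
            (dict(ref="X", alt="T", context="AAAAAXAAAAA"), "DNA base"),
            (dict(context="AAAAAGAAAAA"), "centre"),  # centre G != ref T
            (dict(sample_count=0), "sample_count"),
            (dict(score=1.2), "score"),
        ],
    )
    def test_invalid_records_raise(self, kwargs, match):
        with pytest.raises(InvariantError, match=match):
            make_mutation(**kwargs)


class TestTranscriptSelection:
    def test_longest_cds_wins(self):
        short = make_transcript([(100, 400)], "A" * 300, tid="TR_B")
        long = make_transcript([(100, 1000)], "A" * 900, tid="TR_A")
        chosen = select_longest_transcript([short, long])
        assert chosen["GENEX"].transcript_id == "TR_A"

    def test_single_transcript_kept(self):
        t = make_transcript([(0, 300)], "A" * 300)
        assert select_longest_transcript([t]) == {"GENEX": t}

    def test_tie_broken_by_smallest_transcript_id(self):
        a = make_transcript([(0, 300)], "A" * 300, tid="TR_B")
        b = make_transcript([(0, 300)], "A" * 300, tid="TR_A")
        assert select_longest_transcript([a, b])["GENEX"].transcript_id == "TR_A"
        assert select_longest_transcript([b, a])["GENEX"].transcript_id == "TR_A"


class TestMotifsAndTracks:
    def test_motif_file(self, tmp_path):
        p = tmp_path / "ese.txt"
        p.write_text("GAAGAA\nGAAGAC\n")
        assert len(read_motif_list(p, "ESE")) == 2

    def test_duplicates_deduplicated_and_u_normalised(self, tmp_path):
        p = tmp_path / "ese.txt"
        p.write_text("GAAGAA\ngaagaa\nGAAGAU\n")
        ms = read_motif_list(p, "ESE")
        assert ms.motifs == frozenset({"GAAGAA", "GAAGAT"})

    def test_malformed_motif_reports_line_number(self, tmp_path):
        p = tmp_path / "ese.txt"
        p.write_text("GAAGAA\nGAAG\n")
        with pytest.raises(FormatError, match=":2"):
            read_motif_list(p, "ESE")

    def test_bed_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1 100 200\n")
        track = read_bed_track(p, "DHS")
        assert track.contains("chr1", 100) and track.contains("chr1", 199)
        assert not track.contains("chr1", 200) and not track.contains("chr2", 150)

    def test_track_covered_bases_matches_manual_sum(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t250\nchr2\t0\t10\n")
        track = read_bed_track(p)
        assert track.covered_bases() == 150 + 10  # merged [100,250) + [0,10)
        out = tmp_path / "o.bed"
        write_bed_track(track, out)
        assert read_bed_track(out).covered_bases() == 160

    def test_bad_bed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t200\n")
        with pytest.raises(FormatError, match=":2"):
            read_bed_track(p)

    def test_mirna_fasta_normalises_to_rna(self, tmp_path):
        p = tmp_path / "mir.fa"
        p.write_text(">mir-1\nAUGGCUAGCUAG\n>mir-2\nTGAGGTAGTAGGTTGT\n")
        mirnas = read_mirna_fasta(p)
        assert [m.mature_seq for m in mirnas] == ["AUGGCUAGCUAG", "UGAGGUAGUAGGUUGU"]


class TestMotifUnion:
    def test_paper_scale_union_sizes(self):
        # 200 + 238 sharing 36 -> 402 ESEs; 200 + 176 sharing 60 -> 316 ESSs
        def hexamers(n, skip=0):
            out = []
            i = skip
            while len(out) < n:
                s = ""
                x = i
                for _ in range(6):
                    s += "ACGT"[x % 4]
                    x //= 4
                out.append(s)
                i += 1
            return out

        a = MotifSet("ESE", frozenset(hexamers(200)))
        b = MotifSet("ESE", frozenset(hexamers(238, skip=200 - 36)))
        assert len(union_motif_sets([a, b])) == 402
        c = MotifSet("ESS", frozenset(hexamers(200)))
        d = MotifSet("ESS", frozenset(hexamers(176, skip=200 - 60)))
        assert len(union_motif_sets([c, d])) == 316

    def test_mixed_labels_rejected(self):
        with pytest.raises(ValueError, match="label"):
            union_motif_sets(
                [MotifSet("ESE", frozenset({"GAAGAA"})), MotifSet("ESS", frozenset({"TTTTTT"}))]
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        sets=st.lists(
            st.frozensets(
                st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1, max_size=20
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_union_commutative_associative_idempotent(self, sets):
        msets = [MotifSet("ESE", s) for s in sets]
        u = union_motif_sets(msets)
        assert u.motifs == union_motif_sets(list(reversed(msets))).motifs
        assert union_motif_sets([u, u]).motifs == u.motifs
        assert len(u) <= sum(len(m) for m in msets)


class TestTranscriptFiles:
    def test_bed12_round_trip(self, tmp_path, small_reference):
        bed = tmp_path / "t.bed"
        fa = tmp_path / "cds.fa"
        transcripts = list(small_reference.transcripts.values())
        write_transcripts_bed12(transcripts, bed, fa)
        loaded = read_transcripts_bed12(bed, fa)
        assert {t.transcript_id: t for t in loaded} == small_reference.transcripts

    def test_gff3_loader_agrees_with_bed12(self, tmp_path):
        t = make_transcript([(100, 200), (300, 404)], "A" * 204, tid="TR1", gene="G1")
        fa = tmp_path / "cds.fa"
        fa.write_text(">TR1\n" + "A" * 204 + "\n")
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsyn\tgene\t101\t404\t.\t+\t.\tID=G1;Name=G1\n"
            "chr1\tsyn\tmRNA\t101\t404\t.\t+\t.\tID=TR1;Parent=G1\n"
            "chr1\tsyn\texon\t101\t200\t.\t+\t.\tID=TR1.e1;Parent=TR1\n"
            "chr1\tsyn\texon\t301\t404\t.\t+\t.\tID=TR1.e2;Parent=TR1\n"
            "chr1\tsyn\tCDS\t101\t200\t.\t+\t0\tID=TR1.c1;Parent=TR1\n"
            "chr1\tsyn\tCDS\t301\t404\t.\t+\t1\tID=TR1.c2;Parent=TR1\n"
        )
        [loaded] = read_transcripts_gff3(gff, fa)
        assert loaded == t


class TestSmallTables:
    def test_codon_table_round_trip(self, tmp_path, small_reference):
        from synreg.io import write_codon_table

        p = tmp_path / "codons.tsv"
        write_codon_table(small_reference.codon_table, p)
        assert read_codon_table(p).optimal_codons == small_reference.codon_table.optimal_codons

    def test_gene_rates(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("gene\trate\tcds_length\nG1\t5.44e-05\t13875\n")
        rates = read_gene_rates(p)
        assert rates.rate("G1") == pytest.approx(5.44e-5)
        assert rates.length("G1") == 13875
        assert rates.rate("G2") is None
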