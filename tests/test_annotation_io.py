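"""Genomic data model, GTF/FASTA/TSV round trips and the interval index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncscreen.annotation_io import (
    AnnotationFormatError,
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    genome_span,
    read_annotation,
    read_fasta,
    read_table,
    transcript_length,
    write_annotation,
    write_fasta,
    write_table,
)

GTF_LINE = '{c}\tsrc\texon\t{s}\t{e}\t.\t{st}\t.\tgene_id "{g}"; transcript_id "{t}";\n'


def write_gtf(path, rows):
    with open(path, "w") as fh:
        for c, s, e, strand, g, t in rows:
            fh.write(GTF_LINE.format(c=c, s=s, e=e, st=strand, g=g, t=t))


class TestGTFReading:
    def test_two_exon_lines_one_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("chr1", 1, 100, "+", "g1", "t1"), ("chr1", 201, 300, "+", "g1", "t1")])
        ann = read_annotation(p)
        assert len(ann) == 1
        assert len(ann.transcripts["t1"].exons) == 2

    def test_printed_locus_round_trips_span_4572(self, tmp_path):
        """A transcript spanning chr3:115,636,959-115,641,530 must report a
        4572 bp genomic span under 1-based inclusive coordinates."""
        p = tmp_path / "b.gtf"
        write_gtf(
            p,
            [
                ("chr3", 115_636_959, 115_637_458, "+", "g", "t"),
                ("chr3", 115_638_000, 115_638_699, "+", "g", "t"),
                ("chr3", 115_640_806, 115_641_530, "+", "g", "t"),
            ],
        )
        t = read_annotation(p).transcripts["t"]
        assert genome_span(t) == 4572
        assert transcript_length(t) == 1925  # 500 + 700 + 725 nt exons

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\tsrc\texon\t1\t100\t.\t+\t.\n", "9 tab-separated"),
            (
                'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g";\n',
                "transcript_id",
            ),
            (
                'chr1\tsrc\texon\t100\t1\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
                "end",
            ),
            (
                'chr1\tsrc\texon\t1\t100\t.\t.\t.\tgene_id "g"; transcript_id "t";\n',
                "strand",
            ),
        ],
        ids=["8cols", "missing-attr", "end-lt-start", "strandless"],
    )
    def test_malformed_lines_name_line_number(self, tmp_path, line, match):
        p = tmp_path / "bad.gtf"
        p.write_text(line)
        with pytest.raises(AnnotationFormatError, match="line 1") as exc:
            read_annotation(p)
        assert match in str(exc.value)

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "c.gtf"
        p.write_text(
            "# header\n\n" + GTF_LINE.format(c="chr1", s=5, e=50, st="-", g="g", t="t")
        )
        assert len(read_annotation(p)) == 1

    def test_round_trip_identity(self, tmp_path, make_t):
        transcripts = [
            make_t([(10, 50), (100, 180)], strand="-", tid="tA", gid="gA"),
            make_t([(400, 900)], strand="+", tid="tB", gid="gB", annotated=True),
        ]
        ann = AnnotationSet(transcripts)
        p = tmp_path / "rt.gtf"
        write_annotation(ann, p)
        back = read_annotation(p)
        for t in transcripts:
            b = back.transcripts[t.transcript_id]
            assert b.exons == t.exons
            assert b.gene_id == t.gene_id
            assert b.annotated == t.annotated


class TestLengths:
    def test_hand_examples(self, make_t):
        assert genome_span(make_t([(5, 5)])) == 1
        assert genome_span(make_t([(1, 10), (21, 30)])) == 30
        assert transcript_length(make_t([(1, 200)])) == 200
        assert transcript_length(make_t([(1, 10), (21, 30)])) == 20

    @given(
        st.lists(
            st.tuples(st.integers(1, 10_000), st.integers(1, 500)),
            min_size=1,
            max_size=6,
        )
    )
    def test_span_dominates_length(self, raw):
        # build disjoint sorted exons from (gap, length) pairs
        exons, pos = [], 0
        for gap, length in raw:
            start = pos + gap
            exons.append((start, start + length - 1))
            pos = start + length
        t = TranscriptModel(
            "t", "g", tuple(GenomicInterval("c", s, e, "+") for s, e in exons)
        )
        assert genome_span(t) >= transcript_length(t)
        assert (genome_span(t) == transcript_length(t)) == (len(exons) == 1)


class TestModelInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel(
                "t",
                "g",
                (
                    GenomicInterval("c", 1, 100, "+"),
                    GenomicInterval("c", 50, 150, "+"),
                ),
            )

    def test_mixed_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            TranscriptModel(
                "t",
                "g",
                (
                    GenomicInterval("c", 1, 10, "+"),
                    GenomicInterval("c", 20, 30, "-"),
                ),
            )

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 0, 5, "+")
        with pytest.raises(ValueError):
            GenomicInterval("c", 10, 5, "+")
        with pytest.raises(ValueError):
            GenomicInterval("c", 1, 5, ".")


class TestIntervalIndex:
    def test_query_matches_brute_force(self, rng, make_t):
        transcripts = []
        for i in range(200):
            start = int(rng.integers(1, 50_000))
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], start
            for _ in range(n_ex):
                end = pos + int(rng.integers(50, 400))
                exons.append((pos, end))
                pos = end + int(rng.integers(100, 500)) + 1
            transcripts.append(
                make_t(
                    exons,
                    strand="+" if rng.integers(2) == 0 else "-",
                    chrom=f"chr{int(rng.integers(1, 3))}",
                    tid=f"t{i}",
                    gid=f"g{i}",
                )
            )
        ann = AnnotationSet(transcripts)
        for _ in range(50):
            chrom = f"chr{int(rng.integers(1, 3))}"
            qs = int(rng.integers(1, 60_000))
            qe = qs + int(rng.integers(0, 2_000))
            expected = sorted(
                (
                    t.transcript_id
                    for t in transcripts
                    if t.chrom == chrom and t.start <= qe and qs <= t.end
                ),
            )
            got = sorted(t.transcript_id for t in ann.query(chrom, qs, qe))
            assert got == expected


class TestSequenceAndTableIO:
    def test_fasta_round_trip_and_alphabets(self, tmp_path):
        p = tmp_path / "s.fa"
        p.write_text(">a\nacgu\n>b\nACGT\n")
        seqs = read_fasta(p)
        assert seqs == {"a": "ACGU", "b": "ACGT"}
        q = tmp_path / "rt.fa"
        write_fasta(seqs, q)
        assert read_fasta(q) == seqs

    def test_empty_fasta(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        assert read_fasta(p) == {}

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "d.fa"
        p.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.5, 2.0], [0.0, 7.25], [3.0, 4.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
        p = tmp_path / "m.tsv"
        write_table(df, p)
        back = read_table(p)
        pd.testing.assert_frame_equal(back, df)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\ts1\ts2\ng1\t1\toops\n")
        with pytest.raises(ValueError):
            read_table(p)
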