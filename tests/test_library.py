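"""Maximal segment library: aggregation, sequences, FASTA dialect, summary."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txseg.annotation import GeneModel, GenomeInterval, Transcript, reverse_complement
from txseg.fixtures import (
    make_random_transcriptome,
    make_toy_gene,
    oracle_check_library,
    toy_gene_G,
    ToyGeneSpec,
)
from txseg.library import (
    build_segment_library,
    read_segment_fasta,
    segment_gene,
    summarize_library,
    write_segment_fasta,
    write_summary_tsv,
    segments_to_bed12,
)


def test_toy_library_is_exactly_the_four_maximal_segments(toy_segments):
    got = sorted(
        (s.exs, s.loc, s.end, s.width, tuple(sorted(s.txs)))
        for s in toy_segments
    )
    assert got == [
        ((1,), 0, 300, 300, ("Tx1", "Tx2")),
        ((1, 2, 3), 201, 699, 298, ("Tx1",)),
        ((1, 3), 201, 699, 198, ("Tx2",)),
        ((3,), 600, 900, 300, ("Tx1", "Tx2")),
    ]


def test_segment_ids_are_deterministic_ordinals(toy_segments):
    assert [s.seg_id for s in toy_segments] == [
        f"SEG{i:07d}" for i in range(1, 5)
    ]


def test_sequences_concatenate_bin_portions_without_gaps(toy, toy_segments):
    gene, genome = toy
    chrom = genome.sequence("chrG")
    s2 = next(s for s in toy_segments if s.exs == (1, 2, 3))
    assert s2.sequence == chrom[201:300] + chrom[400:500] + chrom[600:699]
    s1 = next(s for s in toy_segments if s.exs == (1,))
    assert s1.sequence == chrom[0:300]


def test_minus_strand_sequences_are_reverse_complemented():
    gene, genome = make_toy_gene(
        ToyGeneSpec(
            "m",
            "chrM",
            "-",
            {"T1": [(0, 120), (200, 320)], "T2": [(0, 120), (200, 320)]},
            seed=1,
        )
    )
    (seg,) = build_segment_library([gene], genome, 50)
    chrom = genome.sequence("chrM")
    expected = reverse_complement(chrom[200:320]) + reverse_complement(
        chrom[0:120]
    )
    assert seg.sequence == expected
    assert seg.exs == (1, 2)


def test_segment_fasta_header_dialect_is_bit_exact(tmp_path, toy_segments):
    path = tmp_path / "lib.fa"
    write_segment_fasta(toy_segments, path)
    lines = path.read_text().splitlines()
    s2 = next(s for s in toy_segments if s.exs == (1, 2, 3))
    expected = (
        f">{s2.seg_id} gene=G;chr=chrG;strand=+;exs=1,2,3;"
        "segStart=201;segEnd=699;txs=Tx1"
    )
    assert expected in lines


def test_segment_fasta_round_trip_preserves_all_fields(tmp_path, toy_segments):
    path = tmp_path / "lib.fa"
    write_segment_fasta(toy_segments, path)
    back = read_segment_fasta(path)
    assert back == toy_segments


def test_spans_are_reconstructible_from_header_fields(tmp_path):
    from txseg.library import attach_spans

    genes, genome = make_random_transcriptome(6, seed=17)
    segs = build_segment_library(genes, genome, 80)
    path = tmp_path / "lib.fa"
    write_segment_fasta(segs, path)
    back = attach_spans(read_segment_fasta(path), genes)
    assert [s.genomic_spans for s in back] == [s.genomic_spans for s in segs]


def test_empty_library_round_trips(tmp_path):
    path = tmp_path / "empty.fa"
    write_segment_fasta([], path)
    assert read_segment_fasta(path) == []


def test_duplicate_segment_id_is_a_format_error(tmp_path, toy_segments):
    path = tmp_path / "dup.fa"
    rec = (
        ">SEG0000001 gene=G;chr=c;strand=+;exs=1;segStart=0;segEnd=5;txs=T\n"
        "ACGTA\n"
    )
    path.write_text(rec + rec)
    with pytest.raises(ValueError, match="duplicate"):
        read_segment_fasta(path)


def test_toy_summary_compression_matches_hand_arithmetic(toy, toy_segments):
    gene, _ = toy
    s = summarize_library(toy_segments, [gene])
    assert s.total_transcript_bases == 1300
    assert s.total_segment_bases == 1096
    assert s.compression_rate == pytest.approx(1 - 1096 / 1300)
    assert s.n_segments == 4 and s.n_transcripts == 2


def test_large_L_gives_full_transcripts_and_zero_compression(toy):
    gene, genome = toy
    segs = build_segment_library([gene], genome, 10_000)
    s = summarize_library(segs, [gene])
    assert s.n_segments == 2
    assert s.compression_rate == pytest.approx(0.0)


def test_single_transcript_transcriptome_has_zero_compression():
    gene, genome = make_toy_gene(
        ToyGeneSpec("s", "chrS", "+", {"T1": [(0, 150), (250, 400)]}, seed=0)
    )
    segs = build_segment_library([gene], genome, 100)
    s = summarize_library(segs, [gene])
    assert s.compression_rate == 0.0


def test_total_segment_bases_monotone_in_L():
    genes, genome = make_random_transcriptome(20, seed=3)
    prev = -1
    for L in (20, 50, 100, 400):
        segs = build_segment_library(genes, None, L)
        total = sum(s.width for s in segs)
        assert total >= prev
        prev = total


@settings(deadline=None, max_examples=8, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_library_satisfies_definition_oracles_on_random_genes(seed):
    genes, genome = make_random_transcriptome(4, seed=seed)
    for L in (50, 100):
        segs = build_segment_library(genes, genome, L)
        report = oracle_check_library(segs, genes, genome, L)
        assert report.ok(), report.counterexamples[:5]


def test_oracle_flags_a_deleted_segment_as_incomplete(toy, toy_segments):
    gene, genome = toy
    broken = [s for s in toy_segments if s.exs != (1, 2, 3)]
    report = oracle_check_library(broken, [gene], genome, 100)
    assert not report.completeness
    assert any("completeness" in c for c in report.counterexamples)


def test_oracle_flags_an_overextended_segment_as_nondisjoint(toy, toy_segments):
    from dataclasses import replace

    gene, genome = toy
    s1 = next(s for s in toy_segments if s.exs == (1,))
    # stretch the E1-only segment into its sibling's full E1 share: now the
    # pair shares a contiguous path of >= L bases
    bloated = replace(
        s1,
        genomic_spans=((1, 0, 300), (2, 400, 500)),
        width=400,
        sequence=s1.sequence + genome.sequence("chrG")[400:500],
    )
    lib = [bloated] + [s for s in toy_segments if s.exs != (1,)]
    report = oracle_check_library(lib, [gene], genome, 100)
    assert not report.disjointness


def test_summary_tsv_and_bed12_exports(tmp_path, toy, toy_segments):
    gene, _ = toy
    summary = summarize_library(toy_segments, [gene])
    tsv = tmp_path / "summary.tsv"
    write_summary_tsv(summary, tsv)
    lines = tsv.read_text().splitlines()
    assert lines[0] == "metric\ttranscriptome\tsegments"
    assert "total_bases\t1300\t1096" in lines

    bed = tmp_path / "segments.bed"
    segments_to_bed12(toy_segments, bed)
    rows = [l.split("\t") for l in bed.read_text().splitlines()]
    s2_row = next(r for r in rows if r[9] == "3")
    assert s2_row[10] == "99,100,99"
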