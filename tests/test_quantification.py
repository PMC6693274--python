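"""Segment counting rules, PSI arithmetic, normalization, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from txseg.events import enumerate_events, map_event_segments
from txseg.fixtures import ReadSimSpec, simulate_reads
from txseg.quantification import (
    SegmentCountMatrix,
    compute_psi,
    count_from_alignment,
    naive_align_count,
    normalize_counts,
    read_counts_tsv,
    write_counts_tsv,
)


def _write_sam(path, targets, records):
    """Minimal single-end SAM against the given (name, length) targets."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in targets:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for qname, refs in records:
        if not refs:
            lines.append(
                f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII"
            )
        else:
            for k, ref in enumerate(refs):
                flag = 0 if k == 0 else 256
                lines.append(
                    f"{qname}\t{flag}\t{ref}\t1\t60\t4M\t*\t0\t0\tACGT\tIIII"
                )
    path.write_text("\n".join(lines) + "\n")


def test_sam_counting_unique_multi_and_unmapped(tmp_path, toy_segments):
    sam = tmp_path / "aln.sam"
    ids = [s.seg_id for s in toy_segments]
    targets = [(s.seg_id, s.width) for s in toy_segments]
    s2 = next(s.seg_id for s in toy_segments if s.exs == (1, 2, 3))
    s3 = next(s.seg_id for s in toy_segments if s.exs == (1, 3))
    records = (
        [(f"u{i}", [s2]) for i in range(3)]
        + [("v1", [s3])]
        + [("m1", [s2, s3])]
        + [("x1", [])]
    )
    _write_sam(sam, targets, records)
    scm = count_from_alignment(sam, toy_segments, "s1")
    assert int(scm.counts.loc[s2, "s1"]) == 3
    assert int(scm.counts.loc[s3, "s1"]) == 1
    assert scm.ambiguous["s1"] == 1
    assert scm.unmapped["s1"] == 1
    assert scm.total("s1") == 6


def test_sam_counting_rejects_unknown_target(tmp_path, toy_segments):
    sam = tmp_path / "aln.sam"
    _write_sam(sam, [("NOPE", 50)], [("r1", ["NOPE"])])
    with pytest.raises(ValueError, match="unknown segment"):
        count_from_alignment(sam, toy_segments, "s1")


def test_paired_fragments_count_once_per_touched_segment(tmp_path, toy_segments):
    import pysam

    ids = {s.exs: s.seg_id for s in toy_segments}
    s2, s4 = ids[(1, 2, 3)], ids[(3,)]
    sam = tmp_path / "pe.sam"
    header = ["@HD\tVN:1.6"]
    for s in toy_segments:
        header.append(f"@SQ\tSN:{s.seg_id}\tLN:{s.width}")
    rows = [
        f"f1\t67\t{s2}\t1\t60\t4M\t=\t1\t0\tACGT\tIIII",
        f"f1\t131\t{s4}\t1\t60\t4M\t=\t1\t0\tACGT\tIIII",
    ]
    sam.write_text("\n".join(header + rows) + "\n")
    scm = count_from_alignment(sam, toy_segments, "s1", paired=True)
    assert int(scm.counts.loc[s2, "s1"]) == 1
    assert int(scm.counts.loc[s4, "s1"]) == 1
    assert scm.pair_counts == {(s2, s4, "s1"): 1}


def test_naive_aligner_maps_every_toy_window_uniquely(toy, toy_segments):
    gene, genome = toy
    cdna = gene.transcript("Tx1").cdna(genome)
    windows = [cdna[i : i + 100] for i in range(len(cdna) - 99)]
    scm = naive_align_count(windows, toy_segments, "w")
    assert scm.unmapped["w"] == 0
    assert scm.ambiguous["w"] == 0
    assert int(scm.counts["w"].sum()) == len(windows)


def test_naive_aligner_matches_reverse_complement(toy, toy_segments):
    from txseg.annotation import reverse_complement

    gene, genome = toy
    cdna = gene.transcript("Tx2").cdna(genome)
    read = reverse_complement(cdna[50:150])
    scm = naive_align_count([read], toy_segments, "r")
    assert int(scm.counts["r"].sum()) == 1


def test_foreign_read_is_unmapped_and_conservation_holds(toy, toy_segments):
    reads = ["A" * 100, "ACGT" * 25]
    scm = naive_align_count(reads, toy_segments, "x")
    assert scm.unmapped["x"] + scm.ambiguous["x"] + int(
        scm.counts["x"].sum()
    ) == len(reads)


def test_empty_read_set_gives_zero_matrix(toy_segments):
    scm = naive_align_count([], toy_segments, "e")
    assert int(scm.counts["e"].sum()) == 0


def test_psi_worked_example(toy, toy_bins, toy_segments):
    gene, _ = toy
    (ev,) = enumerate_events(gene, toy_bins)
    ev = map_event_segments(ev, toy_segments)
    counts = pd.DataFrame(
        0, index=[s.seg_id for s in toy_segments], columns=["x"]
    )
    counts.loc[ev.S_inc[0], "x"] = 30
    counts.loc[ev.S_alt[0], "x"] = 10
    scm = SegmentCountMatrix(counts)
    table = compute_psi([ev], scm, toy_segments)
    c_inc = 30 / 298
    c_alt = 10 / 198
    assert table.psi.loc[ev.event_id, "x"] == pytest.approx(
        c_inc / (c_inc + c_alt)
    )
    assert table.psi.loc[ev.event_id, "x"] == pytest.approx(0.666, abs=1e-3)


def test_psi_zero_inclusion_is_zero_and_zero_total_is_missing(
    toy, toy_bins, toy_segments
):
    gene, _ = toy
    (ev,) = enumerate_events(gene, toy_bins)
    ev = map_event_segments(ev, toy_segments)
    counts = pd.DataFrame(
        0, index=[s.seg_id for s in toy_segments], columns=["a", "b"]
    )
    counts.loc[ev.S_alt[0], "a"] = 7
    scm = SegmentCountMatrix(counts)
    table = compute_psi([ev], scm, toy_segments)
    assert table.psi.loc[ev.event_id, "a"] == 0.0
    assert math.isnan(table.psi.loc[ev.event_id, "b"])
    assert table.reasons[ev.event_id] == "zero coverage"


def test_normalization_examples(toy_segments):
    one = toy_segments[:1]
    counts = pd.DataFrame([[12]], index=[one[0].seg_id], columns=["x"])
    norm = normalize_counts(SegmentCountMatrix(counts), one)
    assert norm.loc[one[0].seg_id, "x"] == pytest.approx(1e6)

    two = toy_segments[:2]
    counts = pd.DataFrame(
        [[two[0].width], [two[1].width]],
        index=[s.seg_id for s in two],
        columns=["x"],
    )
    norm = normalize_counts(SegmentCountMatrix(counts), two)
    assert np.allclose(norm["x"].values, [5e5, 5e5])


def test_zero_depth_sample_warns_and_is_nan(toy_segments):
    counts = pd.DataFrame(
        0, index=[s.seg_id for s in toy_segments], columns=["z"]
    )
    with pytest.warns(UserWarning, match="zero-depth"):
        norm = normalize_counts(SegmentCountMatrix(counts), toy_segments)
    assert norm["z"].isna().all()


def test_counts_tsv_round_trip(tmp_path, toy_segments):
    counts = pd.DataFrame(
        [[3], [1], [0], [5]],
        index=[s.seg_id for s in toy_segments],
        columns=["s1"],
    )
    scm = SegmentCountMatrix(counts)
    path = tmp_path / "counts.tsv"
    write_counts_tsv(scm, path)
    back = read_counts_tsv(path)
    assert back.counts.equals(scm.counts)


def _expected_psi(gene, genome, segments, event, theta, L):
    """Expected PSI from window-position accounting, independent of the
    counting code: each transcript window lands in the unique segment whose
    sequence contains it."""
    exp = {s.seg_id: 0.0 for s in segments}
    for tx in gene.transcripts:
        cdna = tx.cdna(genome)
        n_pos = len(cdna) - L + 1
        w = theta[tx.tx_id] * n_pos
        per_window = w / n_pos
        for i in range(n_pos):
            window = cdna[i : i + L]
            hits = [s for s in segments if window in s.sequence]
            if len(hits) == 1:
                exp[hits[0].seg_id] += per_window
    inc = sum(exp[s] for s in event.S_inc)
    alt = sum(exp[s] for s in event.S_alt)
    len_inc = sum(s.width for s in segments if s.seg_id in event.S_inc)
    len_alt = sum(s.width for s in segments if s.seg_id in event.S_alt)
    ci, ca = inc / len_inc, alt / len_alt
    return ci / (ci + ca)


def test_psi_recovers_expected_value_within_binomial_error(
    toy, toy_bins, toy_segments
):
    gene, genome = toy
    (ev,) = enumerate_events(gene, toy_bins)
    ev = map_event_segments(ev, toy_segments)
    theta = {"Tx1": 3.0, "Tx2": 1.0}
    expected = _expected_psi(gene, genome, toy_segments, ev, theta, 100)
    for seed in range(5):
        sim = ReadSimSpec(abundances=theta, depth=4000, seed=seed)
        out = simulate_reads([gene], genome, sim)
        scm = naive_align_count(out.reads, toy_segments, "s")
        table = compute_psi([ev], scm, toy_segments)
        est = table.psi.loc[ev.event_id, "s"]
        n_eff = sum(int(scm.counts.loc[s, "s"]) for s in ev.S_inc + ev.S_alt)
        tol = 3 * math.sqrt(expected * (1 - expected) / n_eff)
        assert abs(est - expected) < tol
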