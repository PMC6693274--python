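"""Splicing-event enumeration, segment mapping, coupled-event search."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txseg.annotation import GeneModel, GenomeInterval, Transcript
from txseg.events import (
    enumerate_events,
    find_coupled_event_candidates,
    map_event_segments,
    write_events_tsv,
)
from txseg.fixtures import (
    make_incomplete_annotation_scenario,
    make_random_transcriptome,
    make_toy_gene,
    oracle_enumerate_events,
    ToyGeneSpec,
)
from txseg.library import assign_segment_ids, segment_gene
from txseg.preprocessing import build_exonic_bins


def _gene(gene_id, strand, txs):
    return GeneModel(
        gene_id,
        "c",
        strand,
        [
            Transcript(
                t, gene_id, [GenomeInterval("c", s, e, strand) for s, e in exs]
            )
            for t, exs in txs.items()
        ],
    )


def _events(gene):
    return enumerate_events(gene, build_exonic_bins(gene))


def test_toy_gene_yields_one_skipped_exon_event(toy, toy_bins):
    gene, _ = toy
    (ev,) = enumerate_events(gene, toy_bins)
    assert ev.etype == "SE"
    assert ev.T_inc == frozenset({"Tx1"})
    assert ev.T_alt == frozenset({"Tx2"})
    assert ev.inc_regions == ((400, 500),)


def test_shared_downstream_junction_with_differing_start_is_A5():
    gene = _gene(
        "g", "+", {"T1": [(0, 300), (400, 500)], "T2": [(100, 300), (400, 500)]}
    )
    (ev,) = _events(gene)
    assert ev.etype == "A5"
    assert ev.T_inc == frozenset({"T1"})
    assert ev.inc_regions == ((0, 100),)


def test_single_transcript_gene_has_no_events():
    gene = _gene("g", "+", {"T1": [(0, 100), (200, 300)]})
    assert _events(gene) == []


@pytest.mark.parametrize(
    "txs,etype,region",
    [
        (
            {"T1": [(0, 100), (200, 300)], "T2": [(0, 300)]},
            "RI",
            (100, 200),
        ),
        (
            {
                "T1": [(0, 100), (200, 300), (600, 700)],
                "T2": [(0, 100), (400, 500), (600, 700)],
            },
            "MX",
            (200, 300),
        ),
        (
            {"T1": [(0, 100), (600, 700)], "T2": [(300, 400), (600, 700)]},
            "AF",
            (0, 100),
        ),
        (
            {"T1": [(0, 100), (200, 300)], "T2": [(0, 100), (500, 600)]},
            "AL",
            (200, 300),
        ),
        (
            {
                "T1": [(0, 100), (200, 330), (500, 600)],
                "T2": [(0, 100), (200, 300), (500, 600)],
            },
            "A5",
            (300, 330),
        ),
        (
            {
                "T1": [(0, 100), (170, 300), (500, 600)],
                "T2": [(0, 100), (200, 300), (500, 600)],
            },
            "A3",
            (170, 200),
        ),
    ],
)
def test_event_type_rulebook(txs, etype, region):
    gene = _gene("g", "+", txs)
    evs = _events(gene)
    assert [e.etype for e in evs] == [etype]
    assert evs[0].inc_regions == (region,)


def test_minus_strand_swaps_donor_and_acceptor_roles():
    # same geometry as the A5 case above but on the minus strand: the
    # extension now trails the acceptor, so the event becomes A3
    gene = _gene(
        "g",
        "-",
        {
            "T1": [(0, 100), (200, 330), (500, 600)],
            "T2": [(0, 100), (200, 300), (500, 600)],
        },
    )
    (ev,) = _events(gene)
    assert ev.etype == "A3"
    assert ev.inc_regions == ((300, 330),)


def test_events_deduplicate_across_transcript_pairs():
    gene = _gene(
        "g",
        "+",
        {
            "T1": [(0, 100), (200, 300), (500, 600)],
            "T2": [(0, 100), (500, 600)],
            "T3": [(0, 100), (500, 600)],
        },
    )
    evs = _events(gene)
    assert len(evs) == 1
    assert evs[0].T_inc == frozenset({"T1"})
    assert evs[0].T_alt == frozenset({"T2", "T3"})


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=20_000))
def test_enumeration_agrees_with_interval_arithmetic_oracle(seed):
    genes, _ = make_random_transcriptome(3, seed=seed)
    for gene in genes:
        impl = set()
        for e in _events(gene):
            for r in e.inc_regions:
                impl.add((e.etype, r))
            for r in e.alt_regions:
                impl.add((e.etype, r))
        assert impl == oracle_enumerate_events(gene)


def test_toy_se_event_maps_to_the_junction_segments(toy, toy_bins, toy_segments):
    gene, _ = toy
    (ev,) = enumerate_events(gene, toy_bins)
    ev = map_event_segments(ev, toy_segments)
    by_exs = {s.exs: s.seg_id for s in toy_segments}
    assert ev.S_inc == (by_exs[(1, 2, 3)],)
    assert ev.S_alt == (by_exs[(1, 3)],)
    assert ev.quantifiable


def test_retained_intron_maps_intron_cover_vs_splice_junction():
    gene, genome = make_toy_gene(
        ToyGeneSpec(
            "r", "chrR", "+",
            {"T1": [(0, 100), (200, 300)], "T2": [(0, 300)]},
            seed=0,
        )
    )
    bins = build_exonic_bins(gene)
    _, _, _, segs = segment_gene(gene, 50)
    segs = assign_segment_ids(segs)
    (ev,) = enumerate_events(gene, bins)
    ev = map_event_segments(ev, segs)
    lookup = {s.seg_id: s for s in segs}
    assert all(lookup[s].txs == frozenset({"T2"}) for s in ev.S_inc)
    assert all(lookup[s].txs == frozenset({"T1"}) for s in ev.S_alt)


def test_event_with_no_expressed_segments_is_flagged_unquantifiable(
    toy, toy_bins, toy_segments
):
    gene, _ = toy
    (ev,) = enumerate_events(gene, toy_bins)
    skipping_only = [s for s in toy_segments if s.exs != (1, 2, 3)]
    with pytest.warns(UserWarning, match="unquantifiable"):
        ev = map_event_segments(ev, skipping_only)
    assert not ev.quantifiable
    assert ev.reason == "empty S_inc"


def test_scenario_yields_exactly_one_coupled_candidate():
    sc = make_incomplete_annotation_scenario(seed=5)
    genes = sc.truncated_genes
    bins = {g.gene_id: build_exonic_bins(g) for g in genes}
    events = [e for g in genes for e in enumerate_events(g, bins[g.gene_id])]
    cands = find_coupled_event_candidates(
        genes, events, bins, contig_cutoff=100, strand_filter="+"
    )
    assert len(cands) == 1
    c = cands[0]
    assert c.Tc_inc == frozenset({"A"})
    assert c.contig_len == 300


def test_toy_gene_single_event_has_no_coupled_candidates(toy, toy_bins):
    gene, _ = toy
    events = enumerate_events(gene, toy_bins)
    assert (
        find_coupled_event_candidates([gene], events, {"G": toy_bins}) == []
    )


def test_contig_shorter_than_cutoff_is_excluded():
    sc = make_incomplete_annotation_scenario(seed=5)
    genes = sc.truncated_genes
    bins = {g.gene_id: build_exonic_bins(g) for g in genes}
    events = [e for g in genes for e in enumerate_events(g, bins[g.gene_id])]
    assert (
        find_coupled_event_candidates(genes, events, bins, contig_cutoff=301)
        == []
    )


def test_strand_filter_excludes_other_strand():
    sc = make_incomplete_annotation_scenario(seed=5)
    genes = sc.truncated_genes
    bins = {g.gene_id: build_exonic_bins(g) for g in genes}
    events = [e for g in genes for e in enumerate_events(g, bins[g.gene_id])]
    assert (
        find_coupled_event_candidates(
            genes, events, bins, strand_filter="-"
        )
        == []
    )


def test_events_tsv_has_segment_columns(tmp_path, toy, toy_bins, toy_segments):
    gene, _ = toy
    (ev,) = enumerate_events(gene, toy_bins)
    ev = map_event_segments(ev, toy_segments)
    path = tmp_path / "events.tsv"
    write_events_tsv([ev], path)
    header, row = path.read_text().splitlines()
    cols = dict(zip(header.split("\t"), row.split("\t")))
    assert cols["etype"] == "SE"
    assert cols["S_inc"] and cols["S_alt"]
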