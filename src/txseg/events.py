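"""Local splicing events: enumeration, segment mapping, coupled-event search.

Seven binary event types are recognised from pairwise comparison of
transcript bin paths, following the standard event nomenclature:

* SE  - skipped exon: an internal exon island present in one path, spanned
  by a junction in the other;
* RI  - retained intron: one path covers the intron contiguously, the
  other splices it out;
* A5 / A3 - alternative donor / acceptor: an exon extension contiguous
  with the transcription-upstream / -downstream flank (a transcription
  start-site extension with a shared downstream junction is reported as
  A5, and the symmetric end-site extension as A3);
* MX  - mutually exclusive exons: one internal island in each path between
  shared flanks;
* AF / AL - alternative first / last exon, each with its own junction into
  the shared gene body.

Complex regions are decomposed into binary events island by island; the
exclusion junction of an island is the partner transcript's junction
spanning the island's genomic extent.  Events are deduplicated by their
defining coordinates and their inclusion / alternative transcript sets are
computed over *all* transcripts of the gene, not just the discovering pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .annotation import GeneModel
from .library import Segment
from .preprocessing import ExonicBin

__all__ = [
    "EventRecord",
    "CoupledEventCandidate",
    "enumerate_events",
    "map_event_segments",
    "find_coupled_event_candidates",
    "write_events_tsv",
]

Junction = Tuple[int, int]  # (donor edge coord, acceptor edge coord)
Interval = Tuple[int, int]  # genomic half-open


@dataclass
class EventRecord:
    event_id: str
    gene_id: str
    chrom: str
    strand: str
    etype: str  # SE | RI | MX | A5 | A3 | AF | AL
    inc_regions: Tuple[Interval, ...]
    inc_junctions: Tuple[Junction, ...]
    alt_regions: Tuple[Interval, ...]
    alt_junctions: Tuple[Junction, ...]
    T_inc: FrozenSet[str]
    T_alt: FrozenSet[str]
    # transcription ordinals of the bins flanking the variable region
    up_flank_ord: int = -1
    down_flank_ord: int = 10**9
    S_inc: Tuple[str, ...] = ()
    S_alt: Tuple[str, ...] = ()
    quantifiable: bool = True
    reason: str = ""


@dataclass
class CoupledEventCandidate:
    gene_id: str
    e1: EventRecord
    e2: EventRecord
    Tc_inc: FrozenSet[str]
    contig_len: int


class _GeneView:
    """Precomputed per-gene path/junction structure."""

    def __init__(self, gene: GeneModel, bins: List[ExonicBin]):
        self.gene = gene
        self.bins = bins
        self.strand = gene.strand
        self.paths: Dict[str, List[int]] = {
            tx.tx_id: [i for i, b in enumerate(bins) if tx.tx_id in b.txs]
            for tx in gene.transcripts
        }
        self.junctions: Dict[str, Set[Junction]] = {}
        for tx_id, path in self.paths.items():
            js: Set[Junction] = set()
            for i, j in zip(path, path[1:]):
                if not self.contiguous(i, j):
                    js.add(self.junction(i, j))
            self.junctions[tx_id] = js

    def contiguous(self, i: int, j: int) -> bool:
        a, b = self.bins[i].interval, self.bins[j].interval
        return a.end == b.start if self.strand == "+" else a.start == b.end

    def junction(self, i: int, j: int) -> Junction:
        a, b = self.bins[i].interval, self.bins[j].interval
        if self.strand == "+":
            return (a.end, b.start)
        return (a.start, b.end)

    def span(self, idxs: Sequence[int]) -> Interval:
        lo = min(self.bins[i].interval.start for i in idxs)
        hi = max(self.bins[i].interval.end for i in idxs)
        return (lo, hi)

    def txs_with_junction(self, j: Junction) -> FrozenSet[str]:
        return frozenset(t for t, js in self.junctions.items() if j in js)

    def txs_covering(self, idxs: Sequence[int]) -> FrozenSet[str]:
        need = set(idxs)
        return frozenset(
            t for t, p in self.paths.items() if need.issubset(p)
        )

    def spanning_junction(
        self, tx_id: str, region: Interval
    ) -> Optional[Junction]:
        """The transcript's junction whose intron covers `region`, if any."""
        lo, hi = region
        for d, a in self.junctions[tx_id]:
            left, right = (d, a) if d <= a else (a, d)
            if left <= lo and hi <= right:
                return (d, a)
        return None


def _islands(view: _GeneView, idxs: List[int]) -> List[List[int]]:
    """Split a bin run into genomically contiguous islands."""
    out: List[List[int]] = []
    for i in idxs:
        if out and view.contiguous(out[-1][-1], i):
            out[-1].append(i)
        else:
            out.append([i])
    return out


def _mk_event(
    view: _GeneView,
    etype: str,
    inc_regions,
    inc_junctions,
    alt_regions,
    alt_junctions,
    T_inc,
    T_alt,
    up_ord,
    down_ord,
) -> Optional[EventRecord]:
    if not T_inc or not T_alt or (T_inc & T_alt):
        return None
    gene = view.gene
    key_parts = [f"{a}-{b}" for a, b in inc_junctions] + [
        f"r{a}-{b}" for a, b in inc_regions
    ]
    event_id = f"{gene.gene_id};{etype};{gene.chrom}:{'|'.join(key_parts)}"
    return EventRecord(
        event_id=event_id,
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        etype=etype,
        inc_regions=tuple(inc_regions),
        inc_junctions=tuple(inc_junctions),
        alt_regions=tuple(alt_regions),
        alt_junctions=tuple(alt_junctions),
        T_inc=frozenset(T_inc),
        T_alt=frozenset(T_alt),
        up_flank_ord=up_ord,
        down_flank_ord=down_ord,
    )


def _classify_internal_island(
    view: _GeneView,
    island: List[int],
    path_inc: List[int],
    tx_alt: str,
    a: int,
    b: int,
) -> Optional[EventRecord]:
    """One island between shared flank bins a and b; partner path skips it."""
    region = view.span(island)
    alt_j = view.spanning_junction(tx_alt, region)
    if alt_j is None:
        return None
    up_adj = view.contiguous(a, island[0])
    down_adj = view.contiguous(island[-1], b)
    pos = {bin_idx: k for k, bin_idx in enumerate(path_inc)}
    first, last = island[0], island[-1]
    prev_bin = path_inc[pos[first] - 1]
    next_bin = path_inc[pos[last] + 1]
    T_alt = view.txs_with_junction(alt_j)

    if up_adj and down_adj:
        # retained intron: the island fills the partner's intron
        T_inc = view.txs_covering(island)
        return _mk_event(
            view, "RI", [region], [], [], [alt_j], T_inc, T_alt - T_inc, a, b
        )
    if up_adj:
        j_inc = view.junction(last, next_bin)
        T_inc = view.txs_with_junction(j_inc) & view.txs_covering(island)
        return _mk_event(
            view, "A5", [region], [j_inc], [], [alt_j], T_inc, T_alt, a, b
        )
    if down_adj:
        j_inc = view.junction(prev_bin, first)
        T_inc = view.txs_with_junction(j_inc) & view.txs_covering(island)
        return _mk_event(
            view, "A3", [region], [j_inc], [], [alt_j], T_inc, T_alt, a, b
        )
    j_up = view.junction(prev_bin, first)
    j_down = view.junction(last, next_bin)
    T_inc = view.txs_with_junction(j_up) & view.txs_with_junction(j_down)
    return _mk_event(
        view, "SE", [region], [j_up, j_down], [], [alt_j], T_inc, T_alt, a, b
    )


def _txs_reaching_without_junction(view: _GeneView, f: int) -> FrozenSet[str]:
    """Transcripts whose path reaches bin f from the transcription-upstream
    side without splicing into it (they start at f or flow in contiguously)."""
    out = set()
    for t, p in view.paths.items():
        if f not in p:
            continue
        k = p.index(f)
        if k == 0 or view.contiguous(p[k - 1], f):
            out.add(t)
    return frozenset(out)


def _txs_leaving_without_junction(view: _GeneView, f: int) -> FrozenSet[str]:
    out = set()
    for t, p in view.paths.items():
        if f not in p:
            continue
        k = p.index(f)
        if k == len(p) - 1 or view.contiguous(f, p[k + 1]):
            out.add(t)
    return frozenset(out)


def _txs_spanning(view: _GeneView, region: Interval) -> FrozenSet[str]:
    return frozenset(
        t
        for t in view.paths
        if view.spanning_junction(t, region) is not None
    )


def _head_tail_events(
    view: _GeneView,
    head1: List[int],
    head2: List[int],
    f: int,
    t1: str,
    t2: str,
    tail: bool,
) -> List[EventRecord]:
    """Events at the transcription 5' (head) or 3' (tail) end of a pair.

    Per side: an island contiguous with the first/last shared bin f is a
    splice-site shift (A5/A3 depending on whether the owner splices on or
    terminates there); the owner's terminal island, when not contiguous
    with f, is an alternative first/last exon; islands in between are part
    of a complex terminal structure and yield no binary event.
    """
    events: List[EventRecord] = []
    up_ord = -1 if not tail else f
    down_ord = f if not tail else 10**9

    af_candidates = []  # (region, junction, owner)
    for owner, head in ((t1, head1), (t2, head2)):
        if not head:
            continue
        isl = _islands(view, head)
        nearest = isl[-1] if not tail else isl[0]
        terminal = isl[0] if not tail else isl[-1]
        adjacent = (
            view.contiguous(nearest[-1], f)
            if not tail
            else view.contiguous(f, nearest[0])
        )
        path = view.paths[owner]
        if adjacent:
            region = view.span(nearest)
            owner_terminates = nearest is terminal
            spanners = _txs_spanning(view, region)
            if not tail:
                starters = _txs_reaching_without_junction(view, f)
                if owner_terminates:
                    # transcription start-site extension
                    etype = "A5"
                    T_inc = view.txs_covering(nearest)
                    inc_j: List[Junction] = []
                else:
                    # acceptor shift reached by an upstream splice
                    etype = "A3"
                    k = path.index(nearest[0])
                    j = view.junction(path[k - 1], nearest[0])
                    inc_j = [j]
                    T_inc = view.txs_with_junction(j) & view.txs_covering(
                        nearest
                    )
                T_alt = (spanners | starters) - T_inc - view.txs_covering(
                    [nearest[-1]]
                )
            else:
                enders = _txs_leaving_without_junction(view, f)
                if owner_terminates:
                    etype = "A3"  # end-site extension
                    T_inc = view.txs_covering(nearest)
                    inc_j = []
                else:
                    etype = "A5"  # donor shift followed by a splice
                    k = path.index(nearest[-1])
                    j = view.junction(nearest[-1], path[k + 1])
                    inc_j = [j]
                    T_inc = view.txs_with_junction(j) & view.txs_covering(
                        nearest
                    )
                T_alt = (spanners | enders) - T_inc - view.txs_covering(
                    [nearest[0]]
                )
            ev = _mk_event(
                view, etype, [region], inc_j, [], [], T_inc, T_alt,
                up_ord, down_ord,
            )
            if ev:
                events.append(ev)
            if nearest is terminal:
                continue  # side fully handled by the extension event
        # terminal island: alternative first/last exon candidate
        if terminal is not nearest or not adjacent:
            region = view.span(terminal)
            if not tail:
                k = path.index(terminal[-1])
                j = view.junction(terminal[-1], path[k + 1])
            else:
                k = path.index(terminal[0])
                j = view.junction(path[k - 1], terminal[0])
            af_candidates.append((region, j, owner))

    etype = "AL" if tail else "AF"
    if len(af_candidates) == 2:
        (r1, j1, _o1), (r2, j2, _o2) = af_candidates
        upstream_first = (
            (r1[0] < r2[0]) if view.strand == "+" else (r1[1] > r2[1])
        )
        if not upstream_first:
            r1, j1, r2, j2 = r2, j2, r1, j1
        T_inc = view.txs_with_junction(j1)
        T_alt = view.txs_with_junction(j2)
        ev = _mk_event(
            view, etype, [r1], [j1], [r2], [j2],
            T_inc - T_alt, T_alt - T_inc, up_ord, down_ord,
        )
        if ev:
            events.append(ev)
    elif len(af_candidates) == 1:
        region, j, _owner = af_candidates[0]
        T_inc = view.txs_with_junction(j)
        T_alt = (
            _txs_reaching_without_junction(view, f)
            if not tail
            else _txs_leaving_without_junction(view, f)
        )
        ev = _mk_event(
            view, etype, [region], [j], [], [],
            T_inc, T_alt - T_inc, up_ord, down_ord,
        )
        if ev:
            events.append(ev)
    return events


def enumerate_events(
    gene: GeneModel, bins: List[ExonicBin]
) -> List[EventRecord]:
    """All binary splicing events derivable from pairwise path comparison."""
    view = _GeneView(gene, bins)
    found: Dict[Tuple, EventRecord] = {}

    tx_ids = [t.tx_id for t in gene.transcripts]
    for i1 in range(len(tx_ids)):
        for i2 in range(i1 + 1, len(tx_ids)):
            t1, t2 = tx_ids[i1], tx_ids[i2]
            p1, p2 = view.paths[t1], view.paths[t2]
            common = [b for b in p1 if b in set(p2)]
            if not common:
                continue
            for ev in _pair_events(view, t1, t2, p1, p2, common):
                key = (
                    ev.etype,
                    ev.inc_regions,
                    ev.inc_junctions,
                    ev.alt_regions,
                    ev.alt_junctions,
                )
                found.setdefault(key, ev)

    events = list(found.values())
    events.sort(key=lambda e: (e.up_flank_ord, e.down_flank_ord, e.event_id))
    return events


def _pair_events(view, t1, t2, p1, p2, common) -> List[EventRecord]:
    events: List[EventRecord] = []
    cset = set(common)
    i1 = [k for k, b in enumerate(p1) if b in cset]
    i2 = [k for k, b in enumerate(p2) if b in cset]

    # head
    events.extend(
        _head_tail_events(
            view, p1[: i1[0]], p2[: i2[0]], common[0], t1, t2, False
        )
    )
    # tail
    events.extend(
        _head_tail_events(
            view, p1[i1[-1] + 1 :], p2[i2[-1] + 1 :], common[-1], t1, t2, True
        )
    )
    # internal bubbles
    for k in range(len(common) - 1):
        a, b = common[k], common[k + 1]
        x1 = p1[i1[k] + 1 : i1[k + 1]]
        x2 = p2[i2[k] + 1 : i2[k + 1]]
        if not x1 and not x2:
            continue
        isl1 = _islands(view, x1) if x1 else []
        isl2 = _islands(view, x2) if x2 else []
        if (
            len(isl1) == 1
            and len(isl2) == 1
            and not view.contiguous(a, isl1[0][0])
            and not view.contiguous(isl1[0][-1], b)
            and not view.contiguous(a, isl2[0][0])
            and not view.contiguous(isl2[0][-1], b)
        ):
            ev = _mx_event(view, isl1[0], isl2[0], a, b)
            if ev:
                events.append(ev)
            continue
        for island in isl1:
            ev = _classify_internal_island(view, island, p1, t2, a, b)
            if ev:
                events.append(ev)
        for island in isl2:
            ev = _classify_internal_island(view, island, p2, t1, a, b)
            if ev:
                events.append(ev)
    return events


def _mx_event(view, island1, island2, a, b) -> Optional[EventRecord]:
    r1, r2 = view.span(island1), view.span(island2)
    # order the two exclusive exons in transcription direction
    first_is_1 = (r1[0] < r2[0]) if view.strand == "+" else (r1[1] > r2[1])
    if not first_is_1:
        island1, island2 = island2, island1
        r1, r2 = r2, r1
    j1u = view.junction(a, island1[0])
    j1d = view.junction(island1[-1], b)
    j2u = view.junction(a, island2[0])
    j2d = view.junction(island2[-1], b)
    T_inc = view.txs_with_junction(j1u) & view.txs_with_junction(j1d)
    T_alt = view.txs_with_junction(j2u) & view.txs_with_junction(j2d)
    return _mk_event(
        view,
        "MX",
        [r1],
        [j1u, j1d],
        [r2],
        [j2u, j2d],
        T_inc - T_alt,
        T_alt - T_inc,
        a,
        b,
    )


def _segment_junctions(seg: Segment) -> Set[Junction]:
    js: Set[Junction] = set()
    spans = seg.genomic_spans
    for (b1, l1, r1), (b2, l2, r2) in zip(spans, spans[1:]):
        if seg.strand == "+":
            if r1 != l2:
                js.add((r1, l2))
        else:
            if l1 != r2:
                js.add((l1, r2))
    return js


def _overlaps_regions(seg: Segment, regions: Sequence[Interval]) -> bool:
    for lo, hi in regions:
        for _b, l, r in seg.genomic_spans:
            if l < hi and lo < r:
                return True
    return False


def map_event_segments(
    e: EventRecord, segments: Sequence[Segment]
) -> EventRecord:
    """Fill S_inc / S_alt: segments spanning the event exon or junctions
    while belonging to at least one transcript undergoing that splicing."""
    s_inc: List[str] = []
    s_alt: List[str] = []
    for seg in segments:
        if seg.gene_id != e.gene_id:
            continue
        segj = _segment_junctions(seg)
        if seg.txs & e.T_inc and (
            any(j in segj for j in e.inc_junctions)
            or _overlaps_regions(seg, e.inc_regions)
        ):
            s_inc.append(seg.seg_id)
        if seg.txs & e.T_alt and (
            any(j in segj for j in e.alt_junctions)
            or _overlaps_regions(seg, e.alt_regions)
        ):
            s_alt.append(seg.seg_id)
    quantifiable = bool(s_inc) and bool(s_alt)
    reason = ""
    if not quantifiable:
        reason = "empty S_inc" if not s_inc else "empty S_alt"
        warnings.warn(
            f"event {e.event_id} unquantifiable: {reason}", stacklevel=2
        )
    return replace(
        e,
        S_inc=tuple(sorted(s_inc)),
        S_alt=tuple(sorted(s_alt)),
        quantifiable=quantifiable,
        reason=reason,
    )


def enumerate_and_map_events(
    genes: Sequence[GeneModel], segments: Sequence[Segment]
) -> List[EventRecord]:
    """Enumerate events for every gene and fill their segment sets."""
    from .preprocessing import build_exonic_bins

    out: List[EventRecord] = []
    for gene in genes:
        bins = build_exonic_bins(gene)
        for e in enumerate_events(gene, bins):
            out.append(map_event_segments(e, segments))
    return out


def _event_bound_ords(e: EventRecord) -> Tuple[int, int]:
    return e.up_flank_ord, e.down_flank_ord


def find_coupled_event_candidates(
    genes: Sequence[GeneModel],
    events: Sequence[EventRecord],
    bins_by_gene: Dict[str, List[ExonicBin]],
    contig_cutoff: int = 100,
    etypes: FrozenSet[str] = frozenset({"SE", "A3", "A5"}),
    strand_filter: Optional[str] = None,
) -> List[CoupledEventCandidate]:
    """Ordered event pairs whose inclusion-1 x exclusion-2 combination is
    absent from the annotation and that share a long splice-graph contig.

    ``contig_len`` is the longest run of bins, between the two events and
    consecutive in both paths, shared by a transcript of ``Tc_inc`` and one
    of ``T2_alt``; widths are genomic bases.
    """
    out: List[CoupledEventCandidate] = []
    by_gene: Dict[str, List[EventRecord]] = {}
    for e in events:
        if e.etype in etypes:
            by_gene.setdefault(e.gene_id, []).append(e)
    for gene in genes:
        if strand_filter and gene.strand != strand_filter:
            continue
        evs = sorted(by_gene.get(gene.gene_id, []), key=_event_bound_ords)
        if len(evs) < 2:
            continue
        bins = bins_by_gene[gene.gene_id]
        view = _GeneView(gene, bins)
        for a in range(len(evs)):
            for b in range(a + 1, len(evs)):
                e1, e2 = evs[a], evs[b]
                if e1.down_flank_ord > e2.up_flank_ord:
                    continue  # events overlap or are unordered
                Tc = e1.T_inc & e2.T_inc
                if not Tc or (e1.T_inc & e2.T_alt):
                    continue
                lo, hi = e1.down_flank_ord, e2.up_flank_ord
                contig = _shared_contig_len(view, Tc, e2.T_alt, lo, hi)
                if contig >= contig_cutoff:
                    out.append(
                        CoupledEventCandidate(
                            gene.gene_id, e1, e2, frozenset(Tc), contig
                        )
                    )
    return out


def _shared_contig_len(
    view: _GeneView,
    txs_a: FrozenSet[str],
    txs_b: FrozenSet[str],
    lo_ord: int,
    hi_ord: int,
) -> int:
    """Max width of a bin run between ordinals [lo, hi] consecutive in a
    path from each transcript set."""
    best = 0
    for ta in txs_a:
        pa = [i for i in view.paths[ta] if lo_ord <= i <= hi_ord]
        sa = set(pa)
        nxt_a = {i: j for i, j in zip(pa, pa[1:])}
        for tb in txs_b:
            pb = [i for i in view.paths[tb] if lo_ord <= i <= hi_ord]
            nxt_b = {i: j for i, j in zip(pb, pb[1:])}
            run_start = {i for i in pb if i in sa}
            visited = set()
            for i in sorted(run_start):
                if i in visited:
                    continue
                width = view.bins[i].interval.width()
                cur = i
                visited.add(cur)
                while (
                    cur in nxt_a
                    and cur in nxt_b
                    and nxt_a[cur] == nxt_b[cur]
                ):
                    cur = nxt_a[cur]
                    visited.add(cur)
                    width += view.bins[cur].interval.width()
                best = max(best, width)
    return best


def write_events_tsv(events: Sequence[EventRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "event_id\tgene_id\tetype\tchrom\tstrand\tinc_coords\t"
            "alt_coords\tT_inc\tT_alt\tS_inc\tS_alt\n"
        )
        for e in events:
            inc = ";".join(
                [f"{a}-{b}" for a, b in e.inc_regions]
                + [f"j{a}-{b}" for a, b in e.inc_junctions]
            )
            alt = ";".join(
                [f"{a}-{b}" for a, b in e.alt_regions]
                + [f"j{a}-{b}" for a, b in e.alt_junctions]
            )
            fh.write(
                "\t".join(
                    [
                        e.event_id,
                        e.gene_id,
                        e.etype,
                        e.chrom,
                        e.strand,
                        inc,
                        alt,
                        ",".join(sorted(e.T_inc)),
                        ",".join(sorted(e.T_alt)),
                        ",".join(e.S_inc),
                        ",".join(e.S_alt),
                    ]
                )
                + "\n"
            )
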