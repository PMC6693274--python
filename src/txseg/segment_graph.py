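"""Per-gene splice graph and L-disjoint segment-node construction.

The splice graph has one node per exonic bin and a directed edge between
two bins whenever they are consecutive in at least one transcript.  From it
we derive segment nodes: contiguous stretches of transcript sequence over
which the set of transcripts carrying the local splicing pattern is
constant.  Concretely, slide a window of length ``min(L, transcript
length)`` along each transcript; the window's *pattern set* is the set of
transcripts that contain the window's bin path consecutively (the covering
set of a single bin, or the intersection of the splice-edge supports along
the path).  Maximal runs of window positions with a constant (first bin,
last bin) pair form the segment nodes; aggregation of adjacent equal-set
nodes (see :mod:`txseg.library`) then yields maximal segments.

Nodes are deduplicated genomically across transcripts, so shared gene
regions are emitted once.  Each node's width is at least ``min(L,
transcript length)`` and any two nodes overlap by fewer than L contiguous
bases, which is what lets an error-free read of length L map to exactly
one segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import networkx as nx

from .annotation import GeneModel
from .preprocessing import ExonicBin

__all__ = [
    "SpliceGraph",
    "SegmentNode",
    "SegmentsGraph",
    "build_splice_graph",
    "build_segment_nodes",
    "splice_graph_to_dot",
    "segments_graph_to_dot",
]

# A span is (bin index, start offset, end offset); offsets are measured in
# transcription orientation from the transcription-start edge of the bin.
Span = Tuple[int, int, int]


@dataclass
class SpliceGraph:
    gene: GeneModel
    bins: List[ExonicBin]
    graph: nx.DiGraph  # nodes: bin indices; edge attr 'txs': frozenset
    tx_paths: Dict[str, List[int]]  # tx_id -> bin indices, transcription order

    def edge_txs(self, i: int, j: int) -> FrozenSet[str]:
        return self.graph.edges[i, j]["txs"]


@dataclass
class SegmentNode:
    """An L-disjoint (not necessarily maximal) segment."""

    spans: Tuple[Span, ...]
    txs: FrozenSet[str]

    @property
    def width(self) -> int:
        return sum(e - s for _, s, e in self.spans)

    @property
    def first_bin(self) -> int:
        return self.spans[0][0]


@dataclass
class SegmentsGraph:
    gene: GeneModel
    bins: List[ExonicBin]
    L: int
    nodes: List[SegmentNode]
    graph: nx.DiGraph  # nodes: indices into `nodes`
    tx_node_paths: Dict[str, List[int]]


def build_splice_graph(bins: List[ExonicBin], gene: GeneModel) -> SpliceGraph:
    """Bins as nodes; an edge wherever two bins are consecutive in a transcript."""
    interval_index = {}
    for idx, b in enumerate(bins):
        interval_index[(b.interval.start, b.interval.end)] = idx

    tx_paths: Dict[str, List[int]] = {}
    for tx in gene.transcripts:
        covered = [
            idx
            for idx, b in enumerate(bins)
            if tx.tx_id in b.txs
        ]
        # bins are already in transcription order; a transcript's path is the
        # transcription-ordered subsequence of bins it covers
        tx_paths[tx.tx_id] = covered
        if not covered:
            raise RuntimeError(
                f"transcript {tx.tx_id} covers no bin of gene {gene.gene_id}"
            )

    g = nx.DiGraph()
    g.add_nodes_from(range(len(bins)))
    for tx_id, path in tx_paths.items():
        for i, j in zip(path, path[1:]):
            if g.has_edge(i, j):
                g.edges[i, j]["txs"] = g.edges[i, j]["txs"] | {tx_id}
            else:
                g.add_edge(i, j, txs=frozenset({tx_id}))
    return SpliceGraph(gene, bins, g, tx_paths)


def _window_txs(sg: SpliceGraph, path: List[int], i: int, j: int) -> FrozenSet[str]:
    """Transcripts containing the bin sub-path path[i..j] consecutively."""
    if i == j:
        return sg.bins[path[i]].txs
    txs = sg.edge_txs(path[i], path[i + 1])
    for m in range(i + 1, j):
        txs = txs & sg.edge_txs(path[m], path[m + 1])
    return txs


def _blocks_for_transcript(
    sg: SpliceGraph, path: List[int], L: int
) -> List[Tuple[Tuple[Span, ...], FrozenSet[str]]]:
    """Constant-(first bin, last bin) window blocks along one transcript.

    Returns (spans, txs) per block in transcription order.
    """
    widths = [sg.bins[b].interval.width() for b in path]
    cum = [0]
    for w in widths:
        cum.append(cum[-1] + w)
    T = cum[-1]
    L_eff = min(L, T)
    max_s = T - L_eff

    pts = {0}
    for m in range(1, len(path)):
        if 0 < cum[m] <= max_s:
            pts.add(cum[m])  # window start enters bin m
        q = cum[m] - L_eff + 1
        if 0 < q <= max_s:
            pts.add(q)  # window end enters bin m
    starts = sorted(pts)
    starts.append(max_s + 1)  # sentinel

    import bisect

    blocks = []
    for s_a, s_next in zip(starts, starts[1:]):
        s_b = s_next - 1
        i = bisect.bisect_right(cum, s_a) - 1
        j = bisect.bisect_right(cum, s_a + L_eff - 1) - 1
        txs = _window_txs(sg, path, i, j)
        lo, hi = s_a, s_b + L_eff  # tx-coordinate extent of the block
        spans = []
        for m in range(i, j + 1):
            off_start = max(0, lo - cum[m])
            off_end = min(widths[m], hi - cum[m])
            spans.append((path[m], off_start, off_end))
        blocks.append((tuple(spans), txs))
    return blocks


def build_segment_nodes(sg: SpliceGraph, L: int) -> SegmentsGraph:
    """Construct the segments graph of L-disjoint segment nodes."""
    if L <= 0:
        raise ValueError(f"L must be a positive integer, got {L}")

    nodes: List[SegmentNode] = []
    key_to_idx: Dict[Tuple[Span, ...], int] = {}
    tx_node_paths: Dict[str, List[int]] = {}

    for tx in sg.gene.transcripts:
        path = sg.tx_paths[tx.tx_id]
        seq = []
        for spans, txs in _blocks_for_transcript(sg, path, L):
            if spans in key_to_idx:
                idx = key_to_idx[spans]
                assert nodes[idx].txs == txs, "inconsistent node transcript set"
            else:
                idx = len(nodes)
                key_to_idx[spans] = idx
                nodes.append(SegmentNode(spans, txs))
            seq.append(idx)
        tx_node_paths[tx.tx_id] = seq

    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    for tx_id, seq in tx_node_paths.items():
        for a, b in zip(seq, seq[1:]):
            if g.has_edge(a, b):
                g.edges[a, b]["txs"] = g.edges[a, b]["txs"] | {tx_id}
            else:
                g.add_edge(a, b, txs=frozenset({tx_id}))
    return SegmentsGraph(sg.gene, sg.bins, L, nodes, g, tx_node_paths)


def _dot_escape(s: str) -> str:
    return s.replace('"', r"\"")


def splice_graph_to_dot(sg: SpliceGraph) -> str:
    lines = [f'digraph "{_dot_escape(sg.gene.gene_id)}_splice" {{']
    for idx, b in enumerate(sg.bins):
        label = f"bin{b.bin_id} [{b.interval.start},{b.interval.end})"
        lines.append(f'  n{idx} [label="{_dot_escape(label)}"];')
    for i, j, data in sg.graph.edges(data=True):
        label = ",".join(sorted(data["txs"]))
        lines.append(f'  n{i} -> n{j} [label="{_dot_escape(label)}"];')
    lines.append("}")
    return "\n".join(lines)


def segments_graph_to_dot(g: SegmentsGraph) -> str:
    lines = [f'digraph "{_dot_escape(g.gene.gene_id)}_segments" {{']
    for idx, node in enumerate(g.nodes):
        bins = ",".join(str(g.bins[b].bin_id) for b, _, _ in node.spans)
        label = f"bins {bins} w={node.width} txs={','.join(sorted(node.txs))}"
        lines.append(f'  s{idx} [label="{_dot_escape(label)}"];')
    for i, j in g.graph.edges():
        lines.append(f"  s{i} -> s{j};")
    lines.append("}")
    return "\n".join(lines)
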