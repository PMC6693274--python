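"""Maximal segment aggregation, sequence attachment, FASTA output, summaries.

Aggregation walks the segments graph and merges every edge whose source has
out-degree 1 and whose target has in-degree 1 *and* whose endpoints carry
the same transcript set, concatenating the merged nodes' bin spans.  The
result is the library of maximal L-disjoint segments: no segment is
subsumed by a longer one with the same bins, start and transcript set.

Segment FASTA header dialect (bit-exact, one line per record)::

    >SEG0000001 gene=<gene_id>;chr=<chrom>;strand=<+|->;exs=<bin ids>;segStart=<loc>;segEnd=<end>;txs=<tx ids>

``exs`` lists 1-based exonic-bin ordinals in transcription order.
``segStart`` is the leftmost genomic coordinate (0-based) of the segment's
portion of its transcription-first bin and ``segEnd`` the exclusive right
coordinate of its portion of the transcription-last bin; on the minus
strand segStart can therefore exceed segEnd, reflecting transcription
direction.  Sequences are reported in transcription orientation (reverse
complemented for minus-strand genes) so the library is a drop-in
replacement for a transcriptome FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .annotation import GeneModel, GenomeInterval, GenomeStore, reverse_complement
from .preprocessing import ExonicBin, build_exonic_bins
from .segment_graph import (
    SegmentNode,
    SegmentsGraph,
    Span,
    build_segment_nodes,
    build_splice_graph,
)

__all__ = [
    "Segment",
    "LibrarySummary",
    "aggregate_maximal_segments",
    "finalize_segments",
    "segment_gene",
    "build_segment_library",
    "attach_sequences",
    "write_segment_fasta",
    "read_segment_fasta",
    "attach_spans",
    "summarize_library",
    "write_summary_tsv",
    "segments_to_bed12",
]


@dataclass
class Segment:
    """A maximal L-disjoint segment of a gene."""

    seg_id: str
    gene_id: str
    chrom: str
    strand: str
    exs: Tuple[int, ...]  # 1-based bin ordinals, transcription order
    loc: int  # leftmost genomic coord of portion in transcription-first bin
    end: int  # exclusive right coord of portion in transcription-last bin
    width: int
    txs: FrozenSet[str]
    sequence: str = ""
    # genomic half-open (left, right) per bin portion, transcription order;
    # carries construction detail, excluded from equality
    genomic_spans: Tuple[Tuple[int, int, int], ...] = field(
        default=(), compare=False
    )

    def genomic_positions(self) -> List[int]:
        """Genomic base offsets in transcription order."""
        out: List[int] = []
        for _bin_id, left, right in self.genomic_spans:
            if self.strand == "+":
                out.extend(range(left, right))
            else:
                out.extend(range(right - 1, left - 1, -1))
        return out


def _merge_spans(a: Sequence[Span], b: Sequence[Span]) -> Tuple[Span, ...]:
    """Union of two overlapping same-path span lists (a precedes b)."""
    merged: List[List[int]] = [list(s) for s in a]
    index = {s[0]: k for k, s in enumerate(merged)}
    for bin_idx, o1, o2 in b:
        if bin_idx in index:
            k = index[bin_idx]
            merged[k][1] = min(merged[k][1], o1)
            merged[k][2] = max(merged[k][2], o2)
        else:
            index[bin_idx] = len(merged)
            merged.append([bin_idx, o1, o2])
    return tuple((m[0], m[1], m[2]) for m in merged)


def _merge_nodes(a: SegmentNode, b: SegmentNode) -> SegmentNode:
    if a.txs != b.txs:
        raise RuntimeError(
            "internal error: aggregation across nodes with different "
            "transcript sets"
        )
    return SegmentNode(_merge_spans(a.spans, b.spans), a.txs)


def aggregate_maximal_segments(g: SegmentsGraph) -> SegmentsGraph:
    """Merge chains of degree-1 edges with equal transcript sets."""
    graph = g.graph
    # successor to merge into, when the quoted degree rule and the equal-set
    # premise both hold
    merge_next: Dict[int, int] = {}
    for u, v in graph.edges():
        if (
            graph.out_degree(u) == 1
            and graph.in_degree(v) == 1
            and g.nodes[u].txs == g.nodes[v].txs
        ):
            merge_next[u] = v

    merged_into_prev = set(merge_next.values())
    chain_of: Dict[int, int] = {}  # old node -> new node index
    new_nodes: List[SegmentNode] = []
    for u in range(len(g.nodes)):
        if u in merged_into_prev:
            continue
        node = g.nodes[u]
        chain = [u]
        while chain[-1] in merge_next:
            nxt = merge_next[chain[-1]]
            node = _merge_nodes(node, g.nodes[nxt])
            chain.append(nxt)
        idx = len(new_nodes)
        new_nodes.append(node)
        for member in chain:
            chain_of[member] = idx

    new_paths: Dict[str, List[int]] = {}
    for tx_id, seq in g.tx_node_paths.items():
        out: List[int] = []
        for old in seq:
            new = chain_of[old]
            if not out or out[-1] != new:
                out.append(new)
        new_paths[tx_id] = out

    ng = nx.DiGraph()
    ng.add_nodes_from(range(len(new_nodes)))
    for tx_id, seq in new_paths.items():
        for a, b in zip(seq, seq[1:]):
            if ng.has_edge(a, b):
                ng.edges[a, b]["txs"] = ng.edges[a, b]["txs"] | {tx_id}
            else:
                ng.add_edge(a, b, txs=frozenset({tx_id}))
    return SegmentsGraph(g.gene, g.bins, g.L, new_nodes, ng, new_paths)


def _node_genomic_spans(
    node: SegmentNode, bins: List[ExonicBin], strand: str
) -> Tuple[Tuple[int, int, int], ...]:
    """(bin_id, genomic left, genomic right) per span, transcription order."""
    out = []
    for bin_idx, o1, o2 in node.spans:
        b = bins[bin_idx]
        if strand == "+":
            left, right = b.interval.start + o1, b.interval.start + o2
        else:
            left, right = b.interval.end - o2, b.interval.end - o1
        out.append((b.bin_id, left, right))
    return tuple(out)


def finalize_segments(g: SegmentsGraph) -> List[Segment]:
    """Turn aggregated segment nodes into Segment records (ids unassigned).

    Segments narrower than L can only arise from transcripts shorter than
    L; such a segment is dropped when its genomic path is contiguously
    contained in another segment (literal subsumption).
    """
    gene = g.gene
    candidates: List[Segment] = []
    for node in g.nodes:
        gspans = _node_genomic_spans(node, g.bins, gene.strand)
        if gene.strand == "+":
            loc, end = gspans[0][1], gspans[-1][2]
        else:
            # transcription runs right to left: the segment starts at the
            # right edge of its first portion and ends at the left edge of
            # its last portion
            loc, end = gspans[0][2], gspans[-1][1]
        seg = Segment(
            seg_id="",
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            exs=tuple(bid for bid, _, _ in gspans),
            loc=loc,
            end=end,
            width=node.width,
            txs=node.txs,
            genomic_spans=gspans,
        )
        candidates.append(seg)

    keep: List[Segment] = []
    pos_lists = [tuple(s.genomic_positions()) for s in candidates]
    for i, seg in enumerate(candidates):
        if seg.width >= g.L:
            keep.append(seg)
            continue
        sub = pos_lists[i]
        contained = False
        for j, other in enumerate(candidates):
            if i == j or other.width <= seg.width:
                continue
            hay = pos_lists[j]
            n, m = len(hay), len(sub)
            if any(hay[k : k + m] == sub for k in range(n - m + 1)):
                contained = True
                break
        if not contained:
            keep.append(seg)
    return keep


def segment_gene(gene: GeneModel, L: int):
    """Full per-gene segmentation: bins, splice graph, maximal segments."""
    bins = build_exonic_bins(gene)
    sg = build_splice_graph(bins, gene)
    nodes = build_segment_nodes(sg, L)
    agg = aggregate_maximal_segments(nodes)
    segments = finalize_segments(agg)
    return bins, sg, agg, segments


def _sort_key(seg: Segment):
    return (seg.gene_id, seg.exs[0], seg.genomic_spans[0][1], tuple(sorted(seg.txs)))


def assign_segment_ids(segments: List[Segment]) -> List[Segment]:
    ordered = sorted(segments, key=_sort_key)
    return [
        replace(seg, seg_id=f"SEG{i + 1:07d}") for i, seg in enumerate(ordered)
    ]


def attach_sequences(
    segments: List[Segment], genome: GenomeStore
) -> List[Segment]:
    """Populate transcription-orientation sequences from the genome."""
    out = []
    for seg in segments:
        parts = []
        for _bid, left, right in seg.genomic_spans:
            sub = genome.fetch(GenomeInterval(seg.chrom, left, right))
            parts.append(sub if seg.strand == "+" else reverse_complement(sub))
        out.append(replace(seg, sequence="".join(parts)))
    return out


def build_segment_library(
    genes: Iterable[GeneModel], genome: Optional[GenomeStore], L: int
) -> List[Segment]:
    """Segment every gene, assign deterministic ids, attach sequences."""
    segments: List[Segment] = []
    for gene in genes:
        _, _, _, segs = segment_gene(gene, L)
        segments.extend(segs)
    segments = assign_segment_ids(segments)
    if genome is not None:
        segments = attach_sequences(segments, genome)
    return segments


def attach_spans(
    segments: List[Segment], genes: Iterable[GeneModel]
) -> List[Segment]:
    """Reconstruct per-bin genomic spans for segments read from FASTA.

    The header stores the bin ordinals plus the segment's transcription
    start/end coordinates; interior bins are spanned fully, so the spans
    are recoverable exactly given the annotation."""
    gene_map = {g.gene_id: g for g in genes}
    cache: Dict[str, Dict[int, ExonicBin]] = {}
    out: List[Segment] = []
    for seg in segments:
        if seg.genomic_spans:
            out.append(seg)
            continue
        gene = gene_map[seg.gene_id]
        if seg.gene_id not in cache:
            cache[seg.gene_id] = {
                b.bin_id: b for b in build_exonic_bins(gene)
            }
        bmap = cache[seg.gene_id]
        n = len(seg.exs)
        spans = []
        for k, bid in enumerate(seg.exs):
            iv = bmap[bid].interval
            if seg.strand == "+":
                left = seg.loc if k == 0 else iv.start
                right = seg.end if k == n - 1 else iv.end
            else:
                right = seg.loc if k == 0 else iv.end
                left = seg.end if k == n - 1 else iv.start
            spans.append((bid, left, right))
        out.append(replace(seg, genomic_spans=tuple(spans)))
    return out


def _header(seg: Segment) -> str:
    exs = ",".join(str(b) for b in seg.exs)
    txs = ",".join(sorted(seg.txs))
    return (
        f"{seg.seg_id} gene={seg.gene_id};chr={seg.chrom};strand={seg.strand};"
        f"exs={exs};segStart={seg.loc};segEnd={seg.end};txs={txs}"
    )


def write_segment_fasta(segments: List[Segment], path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{_header(seg)}\n{seg.sequence}\n")


def read_segment_fasta(path) -> List[Segment]:
    segments: List[Segment] = []
    seen = set()
    with open(path) as fh:
        header = None
        seq_parts: List[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    segments.append(_parse_record(header, "".join(seq_parts)))
                header = line[1:]
                seq_parts = []
            elif line:
                seq_parts.append(line)
        if header is not None:
            segments.append(_parse_record(header, "".join(seq_parts)))
    for seg in segments:
        if seg.seg_id in seen:
            raise ValueError(f"duplicate segment id {seg.seg_id}")
        seen.add(seg.seg_id)
    return segments


def _parse_record(header: str, seq: str) -> Segment:
    seg_id, _, meta = header.partition(" ")
    fields = dict(kv.split("=", 1) for kv in meta.split(";") if kv)
    required = {"gene", "chr", "strand", "exs", "segStart", "segEnd", "txs"}
    missing = required - fields.keys()
    if missing:
        raise ValueError(
            f"segment {seg_id}: header missing fields {sorted(missing)}"
        )
    return Segment(
        seg_id=seg_id,
        gene_id=fields["gene"],
        chrom=fields["chr"],
        strand=fields["strand"],
        exs=tuple(int(x) for x in fields["exs"].split(",")),
        loc=int(fields["segStart"]),
        end=int(fields["segEnd"]),
        width=len(seq),
        txs=frozenset(fields["txs"].split(",")),
        sequence=seq,
    )


@dataclass
class LibrarySummary:
    n_segments: int
    n_transcripts: int
    total_segment_bases: int
    total_transcript_bases: int
    compression_rate: float  # 1 - segment bases / transcript bases
    per_gene_segments: Dict[str, int]
    per_gene_transcripts: Dict[str, int]
    segment_lengths: List[int]


def summarize_library(
    segments: List[Segment], genes: Iterable[GeneModel]
) -> LibrarySummary:
    genes = list(genes)
    per_gene_segments: Dict[str, int] = {g.gene_id: 0 for g in genes}
    for seg in segments:
        per_gene_segments[seg.gene_id] = per_gene_segments.get(seg.gene_id, 0) + 1
    per_gene_transcripts = {g.gene_id: len(g.transcripts) for g in genes}
    seg_bases = sum(s.width for s in segments)
    tx_bases = sum(t.length() for g in genes for t in g.transcripts)
    n_tx = sum(len(g.transcripts) for g in genes)
    rate = 1.0 - seg_bases / tx_bases if tx_bases else 0.0
    return LibrarySummary(
        n_segments=len(segments),
        n_transcripts=n_tx,
        total_segment_bases=seg_bases,
        total_transcript_bases=tx_bases,
        compression_rate=rate,
        per_gene_segments=per_gene_segments,
        per_gene_transcripts=per_gene_transcripts,
        segment_lengths=sorted(s.width for s in segments),
    )


def write_summary_tsv(summary: LibrarySummary, path) -> None:
    rows = [
        ("n_sequences", summary.n_transcripts, summary.n_segments),
        (
            "total_bases",
            summary.total_transcript_bases,
            summary.total_segment_bases,
        ),
        ("compression_rate", 0.0, round(summary.compression_rate, 6)),
    ]
    with open(path, "w") as fh:
        fh.write("metric\ttranscriptome\tsegments\n")
        for metric, t, s in rows:
            fh.write(f"{metric}\t{t}\t{s}\n")


def segments_to_bed12(segments: List[Segment], path) -> None:
    """BED12: one record per segment, one block per spanned bin portion."""
    with open(path, "w") as fh:
        for seg in segments:
            spans = sorted((l, r) for _b, l, r in seg.genomic_spans)
            chrom_start = spans[0][0]
            chrom_end = spans[-1][1]
            sizes = ",".join(str(r - l) for l, r in spans)
            starts = ",".join(str(l - chrom_start) for l, r in spans)
            fh.write(
                "\t".join(
                    [
                        seg.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        seg.seg_id,
                        "0",
                        seg.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(spans)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
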