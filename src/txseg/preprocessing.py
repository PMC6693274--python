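"""Shatter a gene's exons into disjoint exonic bins.

Every splicing difference between two isoforms of a gene (skipped exon,
alternative donor/acceptor, retained intron, alternative first/last exon)
falls on a boundary of some bin, because bin boundaries are exactly the
union of all exon start/end coordinates.  Within a bin the set of covering
transcripts is constant at every base.  This step does not depend on the
segment length parameter L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List

from .annotation import GeneModel, GenomeInterval

__all__ = ["ExonicBin", "build_exonic_bins", "bins_to_bed"]


@dataclass(frozen=True)
class ExonicBin:
    """A maximal interval over which the covering transcript set is constant.

    bin_id is a 1-based ordinal in transcription order (ascending genomic
    coordinate for '+' genes, descending for '-').
    """

    bin_id: int
    interval: GenomeInterval
    txs: FrozenSet[str]


def build_exonic_bins(gene: GeneModel) -> List[ExonicBin]:
    """Step 1 of segmentation: disjoint exonic bins in transcription order."""
    boundaries = sorted(
        {c for tx in gene.transcripts for e in tx.exons for c in (e.start, e.end)}
    )
    # Atomic candidate intervals between consecutive boundaries; keep covered.
    raw: List[tuple] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        txs = frozenset(
            tx.tx_id
            for tx in gene.transcripts
            if any(e.start <= lo and hi <= e.end for e in tx.exons)
        )
        if txs:
            raw.append((lo, hi, txs))
    if gene.strand == "-":
        raw.reverse()
    return [
        ExonicBin(i + 1, GenomeInterval(gene.chrom, lo, hi, gene.strand), txs)
        for i, (lo, hi, txs) in enumerate(raw)
    ]


def bins_to_bed(gene: GeneModel, bins: List[ExonicBin], path) -> None:
    """BED6 export: name=gene:bin_id, score=|txs| (0-based half-open)."""
    rows = sorted(bins, key=lambda b: b.interval.start)
    with open(path, "w") as fh:
        for b in rows:
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                f"{gene.gene_id}:{b.bin_id}\t{len(b.txs)}\t{b.interval.strand}\n"
            )
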