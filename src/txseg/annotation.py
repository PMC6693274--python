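"""Genome and transcript-annotation model.

All internal coordinates are 0-based half-open on the forward genomic
strand; GTF input/output converts to and from the 1-based inclusive GTF
convention at the boundary.  A gene is represented as a :class:`GeneModel`
holding one or more :class:`Transcript` objects whose exons are
non-overlapping :class:`GenomeInterval` records in ascending genomic order.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeInterval",
    "Transcript",
    "GeneModel",
    "GenomeStore",
    "AnnotationError",
    "load_annotation",
    "load_genome",
    "write_gtf",
    "reverse_complement",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    """A transcript: ordered, non-overlapping exons on one strand."""

    tx_id: str
    gene_id: str
    exons: List[GenomeInterval]

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"transcript {self.tx_id} has zero exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.tx_id} mixes chromosomes or strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.tx_id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def length(self) -> int:
        return sum(e.width() for e in self.exons)

    def exons_in_transcription_order(self) -> List[GenomeInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cdna(self, genome: "GenomeStore") -> str:
        """Spliced transcript sequence in transcription orientation."""
        parts = [genome.fetch(e) for e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


@dataclass
class GeneModel:
    """A gene: all transcripts share one chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: List[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            if tx.chrom != self.chrom or tx.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: transcript {tx.tx_id} on "
                    f"{tx.chrom}{tx.strand}, expected {self.chrom}{self.strand}"
                )

    def transcript(self, tx_id: str) -> Transcript:
        for tx in self.transcripts:
            if tx.tx_id == tx_id:
                return tx
        raise KeyError(tx_id)

    def span(self) -> GenomeInterval:
        start = min(e.start for t in self.transcripts for e in t.exons)
        end = max(e.end for t in self.transcripts for e in t.exons)
        return GenomeInterval(self.chrom, start, end, self.strand)


class GenomeStore:
    """In-memory genome: chromosome name -> uppercase base string."""

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return self._seqs[chrom]

    def fetch(self, iv: GenomeInterval, reverse_complemented: bool = False) -> str:
        """Sequence of `iv` on the forward strand (optionally revcomp'd)."""
        seq = self.sequence(iv.chrom)
        if iv.end > len(seq):
            raise IndexError(
                f"interval [{iv.start},{iv.end}) beyond {iv.chrom} "
                f"length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if reverse_complemented else sub


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_genome(fasta_path) -> GenomeStore:
    """Read a (possibly gzipped) multi-record genome FASTA."""
    with _open_text(fasta_path) as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    return GenomeStore(seqs)


def write_genome(genome: GenomeStore, fasta_path) -> None:
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(genome.sequence(c)), id=c, description="")
        for c in genome.chroms()
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _parse_gtf_attributes(attr_field: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise AnnotationError(
                f"GTF line {lineno}: malformed attribute {chunk!r}"
            )
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(gtf_path) -> List[GeneModel]:
    """Parse an Ensembl-dialect GTF into GeneModels.

    Only exon features are consumed (gene/transcript rows are allowed but
    redundant; CDS/UTR and other features are ignored).  GTF 1-based
    inclusive coordinates become 0-based half-open.
    """
    exons_by_tx: Dict[str, List[GenomeInterval]] = {}
    tx_gene: Dict[str, str] = {}
    tx_order: List[str] = []
    declared_tx: Dict[str, str] = {}

    with _open_text(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("exon", "transcript"):
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"GTF line {lineno}: non-integer coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from None
            attrs = _parse_gtf_attributes(attr, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationError(
                    f"GTF line {lineno}: missing gene_id/transcript_id"
                )
            tx_id = attrs["transcript_id"]
            if feature == "transcript":
                declared_tx[tx_id] = attrs["gene_id"]
                continue
            if tx_id not in exons_by_tx:
                exons_by_tx[tx_id] = []
                tx_order.append(tx_id)
                tx_gene[tx_id] = attrs["gene_id"]
            exons_by_tx[tx_id].append(GenomeInterval(chrom, start, end, strand))

    for tx_id, gene_id in declared_tx.items():
        if tx_id not in exons_by_tx:
            raise AnnotationError(
                f"transcript {tx_id} (gene {gene_id}) has zero exon records"
            )

    genes: Dict[str, GeneModel] = {}
    gene_order: List[str] = []
    gene_txs: Dict[str, List[Transcript]] = {}
    for tx_id in tx_order:
        tx = Transcript(tx_id, tx_gene[tx_id], exons_by_tx[tx_id])
        gene_txs.setdefault(tx.gene_id, []).append(tx)
        if tx.gene_id not in gene_order:
            gene_order.append(tx.gene_id)
    for gene_id in gene_order:
        txs = gene_txs[gene_id]
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1:
            raise AnnotationError(
                f"gene {gene_id} has transcripts on multiple chromosomes"
            )
        if len(strands) > 1:
            raise AnnotationError(
                f"gene {gene_id} has transcripts on both strands"
            )
        genes[gene_id] = GeneModel(gene_id, txs[0].chrom, txs[0].strand, txs)
    return [genes[g] for g in gene_order]


def write_gtf(genes: Iterable[GeneModel], gtf_path) -> None:
    """Write GeneModels as Ensembl-dialect GTF (1-based inclusive)."""
    with open(gtf_path, "w") as fh:
        for gene in genes:
            span = gene.span()
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "txseg",
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        gene.strand,
                        ".",
                        f'gene_id "{gene.gene_id}";',
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "txseg",
                            "transcript",
                            str(tx.exons[0].start + 1),
                            str(tx.exons[-1].end),
                            ".",
                            gene.strand,
                            ".",
                            f'gene_id "{gene.gene_id}"; '
                            f'transcript_id "{tx.tx_id}";',
                        ]
                    )
                    + "\n"
                )
                for exon in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "txseg",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                gene.strand,
                                ".",
                                f'gene_id "{gene.gene_id}"; '
                                f'transcript_id "{tx.tx_id}";',
                            ]
                        )
                        + "\n"
                    )
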