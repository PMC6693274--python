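"""Segment counting and percent-spliced-in (PSI) computation.

Reads aligned against the segment library become per-sample segment counts
SC(s, x): a read that maps uniquely to one segment increments that
segment's count; a read reported against several segments goes to a
separate ambiguous tally (the library is built so that within-gene
multimapping cannot occur for error-free reads of length <= L, so the
ambiguous tally captures repeats/paralogs only).  For paired-end data each
fragment increments a segment-pair count once and contributes once to each
touched segment's SC.

For a binary splicing event e with inclusion segments S_inc and exclusion
segments S_alt, the PSI in sample x is

    PSI(e, x) = C_inc / (C_inc + C_alt),
    C_side    = sum_s SC(s, x) / sum_s len(s)        (s in S_side)

i.e. counts pooled over a side are normalized by the side's pooled segment
length.  Events with zero total normalized count are reported as missing
(NaN), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import reverse_complement
from .events import EventRecord
from .library import Segment

__all__ = [
    "SegmentCountMatrix",
    "PsiTable",
    "count_from_alignment",
    "naive_align_count",
    "compute_psi",
    "normalize_counts",
    "transcript_compatibility_psi",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass
class SegmentCountMatrix:
    """Segments x samples counts, plus per-sample mapping tallies."""

    counts: pd.DataFrame  # index: seg_id, columns: sample_id, int counts
    ambiguous: Dict[str, int] = field(default_factory=dict)
    unmapped: Dict[str, int] = field(default_factory=dict)
    pair_counts: Dict[Tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def seg_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def total(self, sample: str) -> int:
        return (
            int(self.counts[sample].sum())
            + self.ambiguous.get(sample, 0)
            + self.unmapped.get(sample, 0)
        )


def _empty_counts(seg_ids: Sequence[str], samples: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        0, index=pd.Index(seg_ids, name="seg_id"), columns=list(samples), dtype=int
    )


def count_from_alignment(
    aln_path,
    segments: Sequence[Segment],
    sample_id: str = "sample",
    paired: bool = False,
) -> SegmentCountMatrix:
    """Counts from a SAM/BAM alignment against the segment FASTA.

    Single-end: one increment per uniquely mapped read; reads reported
    against >1 distinct segment go to the ambiguous tally.  Paired-end:
    one pair-count increment per fragment, and each touched segment's SC
    is incremented once per fragment.
    """
    import pysam

    known = {s.seg_id for s in segments}
    counts = _empty_counts([s.seg_id for s in segments], [sample_id])
    ambiguous = 0
    unmapped = 0
    pair_counts: Dict[Tuple[str, str, str], int] = {}

    # collect target sets per read name (handles multi-mappings reported
    # as separate records)
    by_read: Dict[str, List] = {}
    mode = "rb" if str(aln_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(aln_path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                by_read.setdefault(rec.query_name, [])
                continue
            target = rec.reference_name
            if target not in known:
                raise ValueError(
                    f"alignment record {rec.query_name!r} targets unknown "
                    f"segment {target!r}"
                )
            mate = 2 if (paired and rec.is_read2) else 1
            by_read.setdefault(rec.query_name, []).append((mate, target))

    for name, hits in by_read.items():
        if not hits:
            unmapped += 1
            continue
        if not paired:
            targets = {t for _m, t in hits}
            if len(targets) > 1:
                ambiguous += 1
            else:
                counts.loc[hits[0][1], sample_id] += 1
            continue
        m1 = {t for m, t in hits if m == 1}
        m2 = {t for m, t in hits if m == 2}
        if len(m1) > 1 or len(m2) > 1:
            ambiguous += 1
            continue
        touched = sorted(m1 | m2)
        for t in touched:
            counts.loc[t, sample_id] += 1
        if m1 and m2:
            key = tuple(sorted(m1 | m2))
            if len(key) == 1:
                key = (key[0], key[0])
            pair_counts[(key[0], key[1], sample_id)] = (
                pair_counts.get((key[0], key[1], sample_id), 0) + 1
            )

    return SegmentCountMatrix(
        counts,
        ambiguous={sample_id: ambiguous},
        unmapped={sample_id: unmapped},
        pair_counts=pair_counts,
    )


class _ExactMatcher:
    """Exact-substring pseudo-aligner over segment sequences.

    For each queried read length, lazily indexes every window of that
    length (forward and reverse complement) across all segment sequences.
    """

    def __init__(self, segments: Sequence[Segment]):
        self.segments = list(segments)
        self._index: Dict[int, Dict[str, frozenset]] = {}

    def _build(self, k: int) -> Dict[str, frozenset]:
        idx: Dict[str, set] = {}
        for seg in self.segments:
            seq = seg.sequence
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], set()).add(seg.seg_id)
        return {w: frozenset(v) for w, v in idx.items()}

    def targets(self, read: str) -> frozenset:
        k = len(read)
        if k == 0:
            return frozenset()
        if k not in self._index:
            self._index[k] = self._build(k)
        idx = self._index[k]
        hits = idx.get(read, frozenset()) | idx.get(
            reverse_complement(read), frozenset()
        )
        return hits


def naive_align_count(
    reads: Iterable[Tuple[str, str]] | Iterable[str],
    segments: Sequence[Segment],
    sample_id: str = "sample",
) -> SegmentCountMatrix:
    """Exact-match alignment of error-free reads and segment counting.

    ``reads`` is an iterable of sequences or (name, sequence) pairs.  A
    read matching exactly one segment (forward or reverse complement)
    increments that segment; several segments -> ambiguous; none ->
    unmapped.
    """
    matcher = _ExactMatcher(segments)
    counts = _empty_counts([s.seg_id for s in segments], [sample_id])
    col = counts[sample_id].to_dict()
    ambiguous = 0
    unmapped = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        hits = matcher.targets(seq)
        if not hits:
            unmapped += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            col[next(iter(hits))] += 1
    counts[sample_id] = pd.Series(col)
    return SegmentCountMatrix(
        counts, ambiguous={sample_id: ambiguous}, unmapped={sample_id: unmapped}
    )


def merge_count_matrices(mats: Sequence[SegmentCountMatrix]) -> SegmentCountMatrix:
    counts = pd.concat([m.counts for m in mats], axis=1)
    ambiguous = {}
    unmapped = {}
    pair_counts: Dict[Tuple[str, str, str], int] = {}
    for m in mats:
        ambiguous.update(m.ambiguous)
        unmapped.update(m.unmapped)
        pair_counts.update(m.pair_counts)
    return SegmentCountMatrix(counts, ambiguous, unmapped, pair_counts)


@dataclass
class PsiTable:
    """Event x sample PSI values; NaN where undefined."""

    psi: pd.DataFrame
    c_inc: pd.DataFrame
    c_alt: pd.DataFrame
    reasons: Dict[str, str] = field(default_factory=dict)


def compute_psi(
    events: Sequence[EventRecord], scm: SegmentCountMatrix,
    segments: Sequence[Segment],
) -> PsiTable:
    """Length-normalized inclusion ratio per event and sample."""
    seg_len = {s.seg_id: s.width for s in segments}
    samples = scm.sample_ids
    rows_psi, rows_inc, rows_alt = [], [], []
    index = []
    reasons: Dict[str, str] = {}
    for e in events:
        index.append(e.event_id)
        if not e.quantifiable:
            reasons[e.event_id] = e.reason or "unquantifiable"
            rows_psi.append([np.nan] * len(samples))
            rows_inc.append([np.nan] * len(samples))
            rows_alt.append([np.nan] * len(samples))
            continue
        len_inc = sum(seg_len[s] for s in e.S_inc)
        len_alt = sum(seg_len[s] for s in e.S_alt)
        psi_row, inc_row, alt_row = [], [], []
        for x in samples:
            sc_inc = sum(int(scm.counts.loc[s, x]) for s in e.S_inc)
            sc_alt = sum(int(scm.counts.loc[s, x]) for s in e.S_alt)
            c_inc = sc_inc / len_inc
            c_alt = sc_alt / len_alt
            inc_row.append(c_inc)
            alt_row.append(c_alt)
            if c_inc + c_alt > 0:
                psi_row.append(c_inc / (c_inc + c_alt))
            else:
                psi_row.append(np.nan)
                reasons.setdefault(e.event_id, "zero coverage")
        rows_psi.append(psi_row)
        rows_inc.append(inc_row)
        rows_alt.append(alt_row)
    idx = pd.Index(index, name="event_id")
    return PsiTable(
        psi=pd.DataFrame(rows_psi, index=idx, columns=samples),
        c_inc=pd.DataFrame(rows_inc, index=idx, columns=samples),
        c_alt=pd.DataFrame(rows_alt, index=idx, columns=samples),
        reasons=reasons,
    )


def normalize_counts(
    scm: SegmentCountMatrix, segments: Sequence[Segment]
) -> pd.DataFrame:
    """Length- and depth-normalized abundances (TPM-style, per sample):

    rate(s,x) = SC(s,x)/len(s);  norm(s,x) = rate / sum_s rate * 1e6
    """
    import warnings as _warnings

    lengths = pd.Series({s.seg_id: s.width for s in segments})
    rate = scm.counts.div(lengths.reindex(scm.counts.index), axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        _warnings.warn(
            f"zero-depth sample(s): {list(totals.index[zero])}", stacklevel=2
        )
    return rate.div(totals.replace(0, np.nan), axis=1) * 1e6


def transcript_compatibility_psi(
    reads: Iterable[str],
    gene,
    genome,
    events: Sequence[EventRecord],
    read_length: Optional[int] = None,
) -> Dict[str, float]:
    """Baseline PSI from transcript-compatibility read assignment.

    Each read is assigned to the annotated transcripts whose cDNA contains
    it exactly (uniform split among compatible transcripts); transcript
    abundances are the length-normalized assigned read masses, and each
    event's PSI is the inclusion share of abundances using the annotated
    T_inc/T_alt sets.  With an incomplete annotation this estimator is
    forced to give coupled events identical PSI values, which is the bias
    the segment-based estimator avoids.
    """
    cdnas = {tx.tx_id: tx.cdna(genome) for tx in gene.transcripts}
    mass: Dict[str, float] = {t: 0.0 for t in cdnas}
    for read in reads:
        compat = [
            t
            for t, seq in cdnas.items()
            if read in seq or reverse_complement(read) in seq
        ]
        if not compat:
            continue
        w = 1.0 / len(compat)
        for t in compat:
            mass[t] += w
    rl = read_length or 0
    theta = {
        t: mass[t] / max(len(cdnas[t]) - rl + 1, 1) for t in cdnas
    }
    out: Dict[str, float] = {}
    for e in events:
        inc = sum(theta.get(t, 0.0) for t in e.T_inc)
        alt = sum(theta.get(t, 0.0) for t in e.T_alt)
        out[e.event_id] = inc / (inc + alt) if inc + alt > 0 else math.nan
    return out


def write_counts_tsv(scm: SegmentCountMatrix, path) -> None:
    scm.counts.to_csv(path, sep="\t")


def read_counts_tsv(path) -> SegmentCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "seg_id"
    return SegmentCountMatrix(df.astype(int))
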