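"""Synthetic genomes, annotations, reads, and definition-direct oracles.

Everything here exists so the segmentation machinery can be exercised with
known truth and no downloads: toy genes with configurable splicing
structure, a random multi-isoform transcriptome generator, a uniform-
coverage read simulator with a per-read truth table, an incomplete-
annotation scenario with a hidden isoform coupling two distant skipped
exons, and brute-force oracles that check the segment-library properties
(completeness, L-disjointness, maximality) directly from their
definitions.  The oracles deliberately share no code with the segmentation
implementation they check: bins are recomputed per base, completeness by
exhaustive window enumeration over independently assembled cDNA, overlap
by walking genomic base positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .annotation import (
    GeneModel,
    GenomeInterval,
    GenomeStore,
    Transcript,
    reverse_complement,
)
from .library import Segment

__all__ = [
    "ToyGeneSpec",
    "ReadSimSpec",
    "make_toy_gene",
    "toy_gene_G",
    "make_random_transcriptome",
    "simulate_reads",
    "write_fastq",
    "IncompleteAnnotationScenario",
    "make_incomplete_annotation_scenario",
    "OracleReport",
    "oracle_check_library",
    "oracle_exonic_bins",
    "oracle_enumerate_events",
]

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass
class ToyGeneSpec:
    """Explicit exon intervals per transcript; realizability is validated
    by the annotation model."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Dict[str, List[Tuple[int, int]]]
    seed: int = 0
    padding: int = 50  # extra genome sequence past the last exon

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError("spec needs at least one transcript")


def _enforce_branch_distinct_bases(gene: GeneModel, seq: List[str]) -> None:
    """Mutate a chromosome (list of bases, in place) so that at every
    splice-graph branch the alternative continuations start with distinct
    transcribed bases, and at every merge the alternative upstream exons
    end with distinct bases.  This is what makes a random-sequence fixture
    gene behave repeat-free for exact matching: without it, a read ending
    one base past a junction can by chance fit both alternatives."""
    from .preprocessing import build_exonic_bins
    from .segment_graph import build_splice_graph

    bins = build_exonic_bins(gene)
    sg = build_splice_graph(bins, gene)
    plus = gene.strand == "+"
    comp = str.maketrans("ACGT", "TGCA")

    def get(pos: int) -> str:
        return seq[pos] if plus else seq[pos].translate(comp)

    def put(pos: int, base: str) -> None:
        seq[pos] = base if plus else base.translate(comp)

    succ: Dict[int, Set[int]] = {}
    pred: Dict[int, Set[int]] = {}
    for path in sg.tx_paths.values():
        for i, j in zip(path, path[1:]):
            succ.setdefault(i, set()).add(j)
            pred.setdefault(j, set()).add(i)

    def first_pos(k: int) -> int:
        iv = bins[k].interval
        return iv.start if plus else iv.end - 1

    def last_pos(k: int) -> int:
        iv = bins[k].interval
        return iv.end - 1 if plus else iv.start

    for nxts in (v for v in succ.values() if len(v) > 1):
        used: Set[str] = set()
        for j in sorted(nxts):
            pos = first_pos(j)
            base = get(pos)
            if base in used:
                for cand in "ACGT":
                    if cand not in used:
                        put(pos, cand)
                        base = cand
                        break
            used.add(base)
    for prevs in (v for v in pred.values() if len(v) > 1):
        used = set()
        for i in sorted(prevs):
            pos = last_pos(i)
            base = get(pos)
            if base in used:
                for cand in "ACGT":
                    if cand not in used:
                        put(pos, cand)
                        base = cand
                        break
            used.add(base)


def make_toy_gene(spec: ToyGeneSpec) -> Tuple[GeneModel, GenomeStore]:
    """Materialize a ToyGeneSpec as a GeneModel plus a random genome."""
    txs = [
        Transcript(
            tx_id,
            spec.gene_id,
            [GenomeInterval(spec.chrom, s, e, spec.strand) for s, e in exons],
        )
        for tx_id, exons in spec.transcripts.items()
    ]
    gene = GeneModel(spec.gene_id, spec.chrom, spec.strand, txs)
    rng = np.random.default_rng(spec.seed)
    length = gene.span().end + spec.padding
    chars = list(_random_seq(rng, length))
    _enforce_branch_distinct_bases(gene, chars)
    genome = GenomeStore({spec.chrom: "".join(chars)})
    return gene, genome


def toy_gene_G(seed: int = 0) -> Tuple[GeneModel, GenomeStore]:
    """The three-exon, two-isoform worked example used throughout the docs:
    E1=[0,300) and E3=[600,900) shared, E2=[400,500) only in Tx1."""
    spec = ToyGeneSpec(
        gene_id="G",
        chrom="chrG",
        strand="+",
        transcripts={
            "Tx1": [(0, 300), (400, 500), (600, 900)],
            "Tx2": [(0, 300), (600, 900)],
        },
        seed=seed,
    )
    return make_toy_gene(spec)


def _random_gene(
    rng: np.random.Generator, gene_id: str, chrom: str
) -> Tuple[GeneModel, int]:
    """One random multi-isoform gene; returns (gene, genome length needed)."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(3, 8))
    exons: List[Tuple[int, int]] = []
    pos = 0
    for _ in range(n_exons):
        w = int(rng.integers(80, 301))
        exons.append((pos, pos + w))
        pos += w + int(rng.integers(80, 251))

    base = list(exons)
    tx_exons: List[List[Tuple[int, int]]] = [base]
    n_alt = int(rng.integers(1, 4))
    for _ in range(n_alt):
        alt = list(base)
        for _mod in range(int(rng.integers(1, 3))):
            kind = rng.choice(
                ["skip", "retain", "alt_end", "alt_start", "alt_first", "alt_last"]
            )
            if kind == "skip" and len(alt) > 2:
                k = int(rng.integers(1, len(alt) - 1))
                alt.pop(k)
            elif kind == "retain" and len(alt) > 1:
                k = int(rng.integers(0, len(alt) - 1))
                merged = (alt[k][0], alt[k + 1][1])
                alt = alt[:k] + [merged] + alt[k + 2 :]
            elif kind == "alt_end" and len(alt) > 1:
                k = int(rng.integers(0, len(alt) - 1))
                gap = alt[k + 1][0] - alt[k][1]
                if gap > 60:
                    d = int(rng.integers(20, min(gap - 20, 61)))
                    alt[k] = (alt[k][0], alt[k][1] + d)
            elif kind == "alt_start" and len(alt) > 1:
                k = int(rng.integers(1, len(alt)))
                gap = alt[k][0] - alt[k - 1][1]
                if gap > 60:
                    d = int(rng.integers(20, min(gap - 20, 61)))
                    alt[k] = (alt[k][0] - d, alt[k][1])
            elif kind == "alt_first" and len(alt) > 2:
                alt = alt[1:]
            elif kind == "alt_last" and len(alt) > 2:
                alt = alt[:-1]
        if alt != base and alt not in tx_exons:
            tx_exons.append(alt)

    txs = [
        Transcript(
            f"{gene_id}.t{i + 1}",
            gene_id,
            [GenomeInterval(chrom, s, e, strand) for s, e in ex],
        )
        for i, ex in enumerate(tx_exons)
    ]
    gene = GeneModel(gene_id, chrom, strand, txs)
    return gene, pos


def make_random_transcriptome(
    n_genes: int, seed: int
) -> Tuple[List[GeneModel], GenomeStore]:
    """Random multi-isoform genes, one chromosome each, random sequence.

    Deterministic for a fixed seed; uniform random bases keep the genes
    repeat-free with overwhelming probability at read-length scale.
    """
    rng = np.random.default_rng(seed)
    genes: List[GeneModel] = []
    seqs: Dict[str, str] = {}
    for g in range(n_genes):
        gene_id = f"g{g + 1:04d}"
        chrom = f"chr_{gene_id}"
        gene, length = _random_gene(rng, gene_id, chrom)
        genes.append(gene)
        chars = list(_random_seq(rng, length + 50))
        _enforce_branch_distinct_bases(gene, chars)
        seqs[chrom] = "".join(chars)
    return genes, GenomeStore(seqs)


@dataclass
class ReadSimSpec:
    """Uniform-coverage read simulation settings.

    abundances: relative transcript weights (need not sum to 1);
    depth: number of reads (fragments when paired); error_rate: per-base
    substitution probability (default 0: properties are asserted on
    error-free reads).
    """

    abundances: Dict[str, float]
    read_length: int = 100
    depth: int = 10000
    paired: bool = False
    fragment_length: int = 250
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self):
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if self.abundances and not any(self.abundances.values()):
            raise ValueError("abundances must not all be zero")


@dataclass
class SimulatedReads:
    reads: List[Tuple[str, str]]  # (name, sequence); mate 1 when paired
    mates: List[Tuple[str, str]] = field(default_factory=list)
    truth: List[Tuple[str, str, int]] = field(default_factory=list)
    # (read name, source transcript, 0-based start in transcript coords)


def simulate_reads(
    genes: Sequence[GeneModel], genome: GenomeStore, sim: ReadSimSpec
) -> SimulatedReads:
    """Draw reads uniformly along transcripts, weighted by
    abundance x (transcript length - read length + 1)."""
    rng = np.random.default_rng(sim.seed)
    cdnas: Dict[str, str] = {}
    for gene in genes:
        for tx in gene.transcripts:
            if tx.tx_id in sim.abundances:
                cdnas[tx.tx_id] = tx.cdna(genome)
    tx_ids = [t for t in sim.abundances if t in cdnas]
    span = sim.fragment_length if sim.paired else sim.read_length
    n_pos = np.array(
        [max(len(cdnas[t]) - span + 1, 1) for t in tx_ids], dtype=float
    )
    weights = np.array([sim.abundances[t] for t in tx_ids]) * n_pos
    if sim.depth == 0 or not tx_ids or weights.sum() == 0:
        return SimulatedReads([], [], [])
    weights = weights / weights.sum()

    choices = rng.choice(len(tx_ids), size=sim.depth, p=weights)
    reads: List[Tuple[str, str]] = []
    mates: List[Tuple[str, str]] = []
    truth: List[Tuple[str, str, int]] = []
    for i, k in enumerate(choices):
        t = tx_ids[k]
        seq = cdnas[t]
        hi = max(len(seq) - span + 1, 1)
        pos = int(rng.integers(0, hi))
        name = f"read{i + 1}"
        if sim.paired:
            frag = seq[pos : pos + span]
            r1 = frag[: sim.read_length]
            r2 = reverse_complement(frag[-sim.read_length :])
            reads.append((name, _mutate(rng, r1, sim.error_rate)))
            mates.append((name, _mutate(rng, r2, sim.error_rate)))
        else:
            r = seq[pos : pos + sim.read_length]
            reads.append((name, _mutate(rng, r, sim.error_rate)))
        truth.append((name, t, pos))
    return SimulatedReads(reads, mates, truth)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def write_fastq(reads: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: Sequence[Tuple[str, str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\ttranscript\tposition\n")
        for name, tx, pos in truth:
            fh.write(f"{name}\t{tx}\t{pos}\n")


@dataclass
class IncompleteAnnotationScenario:
    """A gene with two distant skipped exons and a hidden isoform that
    combines the inclusion path of the first with the skipping path of the
    second; the truncated annotation lacks exactly that isoform."""

    full_genes: List[GeneModel]
    truncated_genes: List[GeneModel]
    genome: GenomeStore
    abundances: Dict[str, float]
    truth_psi: Dict[str, float]  # event_id -> mixture-truth PSI
    hidden_tx: str


def make_incomplete_annotation_scenario(
    seed: int,
    abundances: Optional[Dict[str, float]] = None,
) -> IncompleteAnnotationScenario:
    """Layout (plus strand): U1(200) - X1(60) - M(300) - X2(60) - D(200),
    introns of 150 bases.  Annotated isoforms: A = U1,X1,M,X2,D and
    C = U1,M,D; hidden isoform H = U1,X1,M,D couples inclusion of X1 with
    skipping of X2.  The 300-base shared exon M is the common splice-graph
    contig between the two events."""
    u1 = (0, 200)
    x1 = (350, 410)
    m = (560, 860)
    x2 = (1010, 1070)
    d = (1220, 1420)
    spec = ToyGeneSpec(
        gene_id="GINC",
        chrom="chrI",
        strand="+",
        transcripts={
            "A": [u1, x1, m, x2, d],
            "C": [u1, m, d],
            "H": [u1, x1, m, d],
        },
        seed=seed,
    )
    full_gene, genome = make_toy_gene(spec)
    truncated_gene = GeneModel(
        "GINC",
        "chrI",
        "+",
        [t for t in full_gene.transcripts if t.tx_id != "H"],
    )
    theta = dict(abundances or {"A": 0.35, "C": 0.35, "H": 0.30})

    from .preprocessing import build_exonic_bins
    from .events import enumerate_events

    bins = build_exonic_bins(full_gene)
    truth: Dict[str, float] = {}
    for e in enumerate_events(full_gene, bins):
        inc = sum(theta.get(t, 0.0) for t in e.T_inc)
        alt = sum(theta.get(t, 0.0) for t in e.T_alt)
        if inc + alt > 0:
            truth[e.event_id] = inc / (inc + alt)
    return IncompleteAnnotationScenario(
        [full_gene], [truncated_gene], genome, theta, truth, "H"
    )


def simulate_usage_counts(
    n_genes: int,
    seed: int,
    n_per_condition: int = 3,
    flagged_fraction: float = 0.0,
    segments_per_gene: int = 3,
    dispersion: float = 0.02,
    log_mean: float = 5.0,
    log_sd: float = 1.5,
):
    """Counts-level differential-usage simulation.

    Each gene has two transcripts with long-tailed (lognormal) expression,
    observed through one private segment each plus one shared segment;
    negative binomial noise with common dispersion.  In flagged genes the
    two transcripts' expression levels are switched across conditions (the
    switch design: total gene output unchanged, usage inverted).  Returns
    (SegmentCountMatrix, segments, DesignSpec, flagged gene ids).
    """
    import pandas as pd

    from .differential import DesignSpec
    from .quantification import SegmentCountMatrix

    rng = np.random.default_rng(seed)
    n = 2 * n_per_condition
    samples = [f"s{i + 1}" for i in range(n)]
    design = DesignSpec(
        samples, ["a"] * n_per_condition + ["b"] * n_per_condition
    )
    r = 1.0 / max(dispersion, 1e-8)
    rows, idx, segments, flagged = [], [], [], []
    for g in range(n_genes):
        gene_id = f"sim{g + 1:04d}"
        is_flagged = rng.random() < flagged_fraction
        theta = rng.lognormal(log_mean, log_sd, size=2)
        theta_b = theta[::-1] if is_flagged else theta
        mus_a = [theta[0], theta[1], theta.sum()]
        mus_b = [theta_b[0], theta_b[1], theta_b.sum()]
        for k in range(segments_per_gene):
            seg_id = f"{gene_id}:S{k + 1}"
            idx.append(seg_id)
            segments.append(
                Segment(
                    seg_id,
                    gene_id,
                    "chrSim",
                    "+",
                    (k + 1,),
                    0,
                    200,
                    200,
                    frozenset({f"{gene_id}.t1"}),
                    "",
                    ((k + 1, 0, 200),),
                )
            )
            mu_a = max(mus_a[min(k, 2)], 0.1)
            mu_b = max(mus_b[min(k, 2)], 0.1)
            a = rng.negative_binomial(r, r / (r + mu_a), size=n_per_condition)
            b = rng.negative_binomial(r, r / (r + mu_b), size=n_per_condition)
            rows.append(np.concatenate([a, b]))
        if is_flagged:
            flagged.append(gene_id)
    counts = pd.DataFrame(rows, index=idx, columns=samples)
    return SegmentCountMatrix(counts), segments, design, flagged


# --------------------------------------------------------------------------
# Definition-direct oracles
# --------------------------------------------------------------------------


@dataclass
class OracleReport:
    completeness: bool
    disjointness: bool
    maximality: bool
    counterexamples: List[str] = field(default_factory=list)

    def ok(self) -> bool:
        return self.completeness and self.disjointness and self.maximality


def oracle_exonic_bins(gene: GeneModel) -> List[Tuple[int, int, frozenset]]:
    """Per-base covering-set labeling, run-length encoded in transcription
    order: the definitional answer build_exonic_bins must reproduce."""
    cover: Dict[int, Set[str]] = {}
    for tx in gene.transcripts:
        for e in tx.exons:
            for p in range(e.start, e.end):
                cover.setdefault(p, set()).add(tx.tx_id)
    positions = sorted(cover)
    runs: List[Tuple[int, int, frozenset]] = []
    for p in positions:
        txs = frozenset(cover[p])
        if runs and runs[-1][1] == p and runs[-1][2] == txs:
            runs[-1] = (runs[-1][0], p + 1, txs)
        else:
            runs.append((p, p + 1, txs))
    if gene.strand == "-":
        runs.reverse()
    return runs


def _segment_positions(seg: Segment) -> List[int]:
    return seg.genomic_positions()


def _max_common_contiguous(path_a: List[int], path_b: List[int]) -> int:
    """Longest run of genomic positions consecutive in both paths."""
    set_b = set(path_b)
    next_b = {p: q for p, q in zip(path_b, path_b[1:])}
    best = 0
    run = 0
    prev = None
    for p in path_a:
        if p in set_b and (run == 0 or next_b.get(prev) == p):
            run += 1
        elif p in set_b:
            run = 1
        else:
            run = 0
        prev = p
        best = max(best, run)
    return best


def oracle_check_library(
    segments: Sequence[Segment],
    genes: Sequence[GeneModel],
    genome: GenomeStore,
    L: int,
) -> OracleReport:
    """Exhaustive check of the three segment-library properties."""
    cx: List[str] = []
    by_gene: Dict[str, List[Segment]] = {}
    for s in segments:
        by_gene.setdefault(s.gene_id, []).append(s)

    completeness = True
    for gene in genes:
        segs = by_gene.get(gene.gene_id, [])
        seqs = [s.sequence for s in segs]
        cdnas = {tx.tx_id: tx.cdna(genome) for tx in gene.transcripts}
        for tx_id, cdna in cdnas.items():
            k = min(L, len(cdna))
            for i in range(len(cdna) - k + 1):
                w = cdna[i : i + k]
                if not any(w in s for s in seqs):
                    completeness = False
                    cx.append(
                        f"completeness: window {tx_id}@{i} (len {k}) of "
                        f"{gene.gene_id} not in any segment"
                    )
                    break
        for s in segs:
            if not any(s.sequence in c for c in cdnas.values()):
                completeness = False
                cx.append(
                    f"completeness: segment {s.seg_id} sequence not a "
                    f"transcript substring"
                )

    disjointness = True
    for gene_id, segs in by_gene.items():
        pos = [_segment_positions(s) for s in segs]
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                ov = _max_common_contiguous(pos[i], pos[j])
                if ov >= L:
                    disjointness = False
                    cx.append(
                        f"disjointness: {segs[i].seg_id} and {segs[j].seg_id}"
                        f" share a contiguous path of {ov} >= L={L}"
                    )

    maximality = True
    for gene_id, segs in by_gene.items():
        for i in range(len(segs)):
            for j in range(len(segs)):
                if i == j:
                    continue
                a, b = segs[i], segs[j]
                if (
                    a.loc == b.loc
                    and a.txs == b.txs
                    and a.exs[: len(b.exs)] == b.exs
                    and a.width > b.width
                ):
                    maximality = False
                    cx.append(
                        f"maximality: {a.seg_id} subsumes {b.seg_id}"
                    )
    return OracleReport(completeness, disjointness, maximality, cx)


# --------------------------------------------------------------------------
# Independent event-enumeration oracle (interval arithmetic, no bin paths)
# --------------------------------------------------------------------------


def oracle_enumerate_events(gene: GeneModel) -> Set[Tuple[str, Tuple[int, int]]]:
    """(etype, variable-region genomic interval) pairs from direct pairwise
    per-base comparison of exon coverage; the inclusion region of an MX
    event is its transcription-first exclusive exon."""
    out: Set[Tuple[str, Tuple[int, int]]] = set()
    plus = gene.strand == "+"
    txs = gene.transcripts
    cover = {
        t.tx_id: set(p for e in t.exons for p in range(e.start, e.end))
        for t in txs
    }
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            t1, t2 = txs[i].tx_id, txs[j].tx_id
            c1, c2 = cover[t1], cover[t2]
            shared = c1 & c2
            if not shared:
                continue
            var = sorted(c1 ^ c2)
            runs: List[Tuple[int, int, str]] = []
            for p in var:
                owner = t1 if p in c1 else t2
                if runs and runs[-1][1] == p and runs[-1][2] == owner:
                    runs[-1] = (runs[-1][0], p + 1, owner)
                else:
                    runs.append((p, p + 1, owner))
            classified: List[Tuple[str, Tuple[int, int], str]] = []
            for lo, hi, owner in runs:
                own = cover[owner]
                left_adj = (lo - 1) in shared
                right_adj = hi in shared
                shared_left = any(p < lo for p in shared)
                shared_right = any(p >= hi for p in shared)
                own_left = any(p < lo for p in own)
                own_right = any(p >= hi for p in own)
                if plus:
                    up_adj, down_adj = left_adj, right_adj
                    shared_up, shared_down = shared_left, shared_right
                    own_up, own_down = own_left, own_right
                else:
                    up_adj, down_adj = right_adj, left_adj
                    shared_up, shared_down = shared_right, shared_left
                    own_up, own_down = own_right, own_left
                if up_adj and down_adj:
                    etype = "RI"
                elif up_adj:  # gene body flows into the run
                    etype = "A5" if own_down else "A3"
                elif down_adj:  # run flows into the gene body
                    etype = "A3" if own_up else "A5"
                elif not shared_up:
                    if own_up:
                        continue  # middle of a complex 5' terminal structure
                    etype = "AF"
                elif not shared_down:
                    if own_down:
                        continue  # middle of a complex 3' terminal structure
                    etype = "AL"
                else:
                    etype = "SE"
                classified.append((etype, (lo, hi), owner))
            # pair internal exclusive exons into MX
            se_runs = [c for c in classified if c[0] == "SE"]
            used: Set[Tuple[int, int]] = set()
            for a in range(len(se_runs)):
                for b in range(a + 1, len(se_runs)):
                    _, ra, oa = se_runs[a]
                    _, rb, ob = se_runs[b]
                    if oa == ob:
                        continue
                    lo, hi = min(ra[1], rb[1]), max(ra[0], rb[0])
                    between_covered = any(
                        lo <= p < hi for p in c1 | c2
                    )
                    # mutual exclusivity holds only when the two exons are
                    # alone between their shared flanks
                    b_lo = max(
                        (p for p in shared if p < min(ra[0], rb[0])),
                        default=-1,
                    )
                    b_hi = min(
                        (p for p in shared if p >= max(ra[1], rb[1])),
                        default=10**9,
                    )
                    others_inside = any(
                        r[0] > b_lo and r[1] <= b_hi
                        for r in runs
                        if (r[0], r[1]) not in (ra, rb)
                    )
                    if lo <= hi and not between_covered and not others_inside:
                        out.add(("MX", ra))
                        out.add(("MX", rb))
                        used.add(ra)
                        used.add(rb)
            for etype, region, _owner in classified:
                if etype == "SE" and region in used:
                    continue
                out.add((etype, region))
    return out
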