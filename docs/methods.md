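# Methods

## Problem setting

Alternatively spliced isoforms of a gene share most of their sequence, so
aligning reads against a transcriptome FASTA multi-maps a large fraction
of them and forces a probabilistic quantification step before any
analysis. `txseg` replaces the transcriptome with a library of maximal
L-disjoint segments: sequences that retain all information of the
annotation (completeness), cannot both receive the same error-free read
of length ≥ L (L-disjointness), and are as long as the splice-graph
branch structure allows (maximality, which stabilizes counts — short
segments have low means and high relative variance). Segment counts from
pseudo-alignment are then used directly for PSI estimation and
differential testing.

## Segmentation

**Coordinates.** Everything internal is 0-based half-open on the forward
genomic strand; GTF (1-based inclusive, Ensembl attribute dialect) is
converted at the boundary. Only gene/transcript/exon features are
consumed; a gene whose transcripts span two strands or chromosomes is
rejected because the per-gene splice graph assumes a single axis.

**Step 1 — exonic bins.** Bin boundaries are the union of all exon start
and end coordinates of the gene, restricted to covered bases; within a
bin the covering transcript set is constant at every base. Retained
introns need no special case: the retaining transcript's exon covers the
intron, so shattering produces the intron bin automatically. Adjacent
bins with identical transcript sets are not merged — a boundary implies
some transcript starts, ends or splices there. Bins are numbered in
transcription order (descending genomic coordinate on the minus strand),
and the step is independent of L.

**Step 2 — segment nodes.** For each transcript, slide a window of
length min(L, transcript length) along its spliced sequence. A window's
*pattern set* is the set of transcripts containing its bin path
consecutively: the covering set of a single bin, or the intersection of
splice-edge supports along the path. Window positions with a constant
(first bin, last bin) pair form blocks; blocks are the segment nodes,
deduplicated genomically across transcripts. Every node's width is at
least min(L, transcript length), and any two nodes overlap by at most
L−1 contiguous bases.

**Step 3 — maximal segments.** In the segments graph (edge = direct
precedence in some transcript), an edge whose source has out-degree 1 and
whose target has in-degree 1 joins nodes carried by the same transcripts;
such chains are merged into one segment. Equality of the two nodes'
transcript sets is checked explicitly rather than assumed: a transcript
whose start coincides with a bin boundary mid-path creates a degree-1
edge between nodes with *different* sets, and such edges are left
unmerged (merging would put windows with different pattern sets inside
one segment). A segment narrower than L can only arise from a transcript
shorter than L; it is dropped when its genomic path is contiguously
contained in another segment.

Why this construction satisfies the three properties: every length-≤L
window of every transcript lies inside the segment built from its block
(completeness, forward direction), and each segment is a contiguous piece
of some transcript (reverse direction). If two distinct segments shared a
contiguous genomic stretch of ≥ L bases, that stretch would contain a
full window belonging to both segments' blocks; block membership is a
function of the window itself, so the two blocks — and hence the
segments, whose extension at every step depends only on the pattern set —
would be identical, a contradiction. Maximality follows because block
extension is deterministic: two segments with the same start, bins and
transcript set arise from the same block and cannot differ in width.
These arguments are not relied on in testing: a definition-direct oracle
(exhaustive window enumeration, longest-common-contiguous-path scan,
subsumption scan) verifies all three properties on randomized fixture
transcriptomes.

**Determinism.** Segments are sorted by (gene, first bin, start
coordinate, transcript set) and numbered `SEG<7-digit>`; repeated runs
are byte-identical. FASTA headers carry gene, chromosome, strand, bin
ordinals, the transcription start/end coordinates of the segment
(descending on the minus strand), and the transcript set; sequences are
written in transcription orientation so the library behaves like a
transcriptome FASTA for any aligner. Per-bin spans are exactly
recoverable from the header plus the annotation (`attach_spans`).

## Splicing events

Events are enumerated by pairwise comparison of transcript bin paths and
deduplicated by their defining coordinates; inclusion/alternative
transcript sets are then recomputed over all transcripts of the gene via
junction membership and bin coverage. The rulebook, applied island by
island inside each "bubble" between shared bins (complex regions
decompose into binary events):

* island filling the partner's intron contiguously on both sides — RI
  (inclusion = transcripts covering the intron);
* island contiguous with the upstream flank — A5 when the owner splices
  on afterwards (donor shift) or, at the transcript 3' end, A3 (end-site
  extension); island contiguous with the downstream flank — A3 when the
  owner arrives by a splice (acceptor shift) or A5 at the transcript 5'
  end (start-site extension with shared downstream junction);
* internal island adjacent to neither flank — SE, with the exclusion
  junction taken as the partner's junction spanning the island;
* exactly one non-adjacent internal island per path between the same
  flanks — MX (inclusion = transcription-first exon);
* a transcript-terminal exon with its own junction into the shared body —
  AF/AL; islands between a terminal exon and the body that are part of a
  complex terminal structure yield no binary event.

Event-to-segment mapping selects segments that span the event exon or an
inclusion junction and belong to at least one inclusion transcript
(symmetrically for the exclusion side); an event whose side maps to no
segment is flagged unquantifiable with a warning and reported as missing
rather than 0. A pure start/end-site extension has no discriminating
exclusion junction and is typically flagged this way.

The coupled-event candidate search considers ordered event pairs
(e₁, e₂) of configurable types (default SE/A3/A5, matching the original
search conditions) where some transcript includes both events' inclusion
forms, no transcript combines inclusion of e₁ with exclusion of e₂ (the
potentially missing isoform), and the two events share a splice-graph
contig of at least 100 genomic bases (default cutoff) between them,
measured as the widest bin run consecutive in a path from each of the two
transcript sets. Strand is a filter argument, not hard-coded.

## Quantification

Single-end counting increments a segment once per uniquely mapped read;
reads hitting several segments go to a separate ambiguous tally (the
library makes within-gene multimapping impossible for error-free reads,
so the tally captures repeats and paralogs, which the method does not
attempt to resolve). Paired-end fragments increment one segment-pair
count and contribute once to each touched segment, avoiding
double-weighting of junction-straddling fragments. SAM/BAM input is read
with pysam; an internal exact-substring matcher (hash index over all
length-k windows of the segment sequences, forward and reverse
complement) serves as the error-free test aligner.

PSI follows the pooled, length-normalized ratio given in the README.
Zero-coverage events are missing (NaN with a reason code), never 0 or
0.5. The TPM-style normalization rate(s,x)=SC/len, scaled to 10⁶, is
provided as a convenience; proper length normalization under complex
splicing is an open modelling question and deliberately not attempted.

The transcript-compatibility baseline (`transcript_compatibility_psi`)
assigns each read uniformly across the annotated transcripts whose cDNA
contains it, length-normalizes the assigned mass, and computes event PSI
from those abundances. It exists to demonstrate the coupling artifact:
with a hidden isoform joining two events, the annotated inclusion and
exclusion sets of both events coincide, so its two PSI values are equal
by construction.

## Differential testing

Segment usage: per gene and segment, counts for (segment, rest of gene)
across samples enter a negative binomial GLM with sample effects, a bin
effect, and a condition×bin interaction; the interaction is tested by a
1-df likelihood-ratio chi-square. Dispersion is a per-gene common value
estimated by matching the Pearson chi-square of the null fit to its
residual degrees of freedom — plain small-sample MLE underestimates the
dispersion and inflates the LRT, and the Pearson match was chosen for
being conservative at 3v3 designs (verified on null simulations). The
trend-shrinkage machinery of the full differential-exon-usage method is
intentionally not reproduced — the counting statistic, not the testing
model, is the contribution here — and `export_for_dexseq` writes a
flattened exonic-part GFF plus per-sample count files so the external
tool can be used at full fidelity. Genes are summarized by the
Šidák-corrected minimum segment p-value (the aggregation rule is a
package choice; only gene-level BH control is prescribed), then BH across
genes. Median-of-ratios size factors are computed for normalization
(sample fixed effects absorb depth inside the GLM).

Differential PSI: per event, ordinary least squares of PSI on the
two-level condition with a t-test on the condition coefficient and BH
across events; constant-PSI or under-observed events are flagged
degenerate with p = 1 or missing.

## Synthetic data and oracles

The fixture generator produces toy genes from explicit exon layouts, and
random multi-isoform transcriptomes (3–7 exons of 80–300 bases, introns
80–250, 2–4 isoforms derived by skipping, intron retention,
donor/acceptor shifts and alternative first/last exons), each gene on its
own chromosome with uniform random sequence. At every splice-graph branch
the generator forces the alternative continuations to start (and merge
sides to end) with distinct bases; without this, a read ending one base
past a junction can by chance fit both alternatives, which is exactly the
repeat ambiguity the repeat-free assumption excludes. Read simulation is
uniform-coverage: transcripts drawn proportionally to
abundance × (length − read length + 1), positions uniform, optional
substitution errors (all properties are asserted at error rate 0), with a
per-read truth table. Defaults mirror common short-read designs: read
length 100, L equal to read length.

The incomplete-annotation scenario uses exon layout
U1(200)–X1(60)–M(300)–X2(60)–D(200) with 150-base introns on the plus
strand: annotated isoforms A = U1·X1·M·X2·D and C = U1·M·D, hidden
isoform H = U1·X1·M·D at abundances (0.35, 0.35, 0.30) — the hidden
isoform expressed high enough that its absence matters, the 300-base M
exon long enough to exceed the 100-base contig cutoff, and the short
cassette exons keeping the inclusion segments close in effective length
to the exclusion junctions. Truth PSI is the isoform-mixture share
computed from the full annotation.

The oracles are definition-direct and share no code with the
implementations they check: bins by per-base labeling and run-length
encoding; events by per-base interval arithmetic over exon coverage;
library properties by exhaustive window enumeration against independently
assembled cDNA, longest-common-contiguous genomic path between segment
pairs, and a subsumption scan.

## Numerical and testing choices

* PSI recovery is asserted against the estimator's expectation under the
  known mixture, computed by exhaustive window accounting. The sampling
  error of the pooled ratio is propagated by the delta method,
  σ ≈ ψ(1−ψ)·√(1/N_inc + 1/N_alt), which reduces to the binomial formula
  √(ψ(1−ψ)/N) when the two sides are balanced; over 50 seeded replicates
  the suite requires no replicate beyond 4σ, at most one beyond 3σ, and
  mean standardized error within 3/√50 — the behaviour of honest
  sampling noise.
* Because segment counts are normalized by segment length while reads
  can start only at length − L + 1 positions, PSI has a known O(L/len)
  finite-length bias relative to the pure mixture fraction; at the
  fixture geometry it stays below 0.06 and is part of what the
  incomplete-annotation error budget (< 0.1) absorbs.
* Usage-test simulations place two transcripts per gene (one private
  segment each plus one shared), lognormal expression with σ = 1.5 —
  long-tailed, so the two isoforms of a gene are usually well separated,
  as in expression data — and NB dispersion 0.02. Problem sizes in the
  default suite (200-gene oracle sweeps, 1000-gene null calibrations,
  depth 10⁵ for the incomplete-annotation comparison) were chosen to keep
  Monte-Carlo error well inside the asserted bounds.
* Hypothesis-based property tests draw only the generator seed, keeping
  every example reproducible.

## What the fixtures do and do not show

Fixture genomes are uniform random sequence: they exercise the
combinatorial splicing structure but contain no repeats, paralogs, GC or
positional coverage bias, and no sequencing error. Passing tests
demonstrate the structural guarantees (completeness, disjointness,
maximality, unique mapping, unbiased local PSI) and the statistical
calibration of the tests under the stated noise models — not robustness
to alignment error or bias correction, which are outside the method's
scope by design. Overlapping genes are processed independently
(cross-gene segment graphs are future work), so reads from genomically
overlapping loci can still multi-map across genes. Single-segment genes
are excluded from usage testing; transcripts shorter than L yield whole-
transcript segments unless contiguously subsumed.
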