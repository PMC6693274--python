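"""Why local segment counts beat transcript assignment when the
annotation is incomplete.

A gene carries two distant skipped exons; a hidden isoform couples the
inclusion of the first with the skipping of the second and is missing
from the annotation used for analysis.  Transcript-compatibility
assignment is then forced to report the same PSI for both events, while
segment counts, being local, stay close to the truth.
"""

from txseg.events import enumerate_and_map_events
from txseg.fixtures import (
    ReadSimSpec,
    make_incomplete_annotation_scenario,
    simulate_reads,
)
from txseg.library import build_segment_library
from txseg.quantification import (
    compute_psi,
    naive_align_count,
    transcript_compatibility_psi,
)

sc = make_incomplete_annotation_scenario(seed=0)
genes, genome = sc.truncated_genes, sc.genome
segments = build_segment_library(genes, genome, L=100)

sim = ReadSimSpec(abundances=sc.abundances, depth=100_000, seed=1)
reads = simulate_reads(sc.full_genes, genome, sim)  # truth includes H
scm = naive_align_count(reads.reads, segments, "x")

events = enumerate_and_map_events(genes, segments)
table = compute_psi(events, scm, segments)
naive = transcript_compatibility_psi(
    [seq for _n, seq in reads.reads], genes[0], genome, events,
    read_length=100,
)

print("event      truth   segment-PSI   transcript-PSI")
for i, e in enumerate(events, 1):
    truth = sc.truth_psi[e.event_id]
    seg = table.psi.loc[e.event_id, "x"]
    print(f"event {i}    {truth:.3f}   {seg:.3f}         {naive[e.event_id]:.3f}")
print(
    "\nThe transcript-based estimates are identical for both events (the "
    "coupling artifact); the segment-based estimates track the truth."
)
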