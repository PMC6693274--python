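"""Differential segment usage between two conditions.

Simulates segment counts for 60 genes (3 vs 3 samples); in a quarter of
them the two transcripts' expression levels are switched across
conditions while total gene output stays constant - the situation
gene-level differential expression misses but usage testing catches.
Each segment is tested with a negative binomial GLM likelihood-ratio
test; gene-level p-values are Sidak-corrected minima with BH FDR control
across genes.
"""

from txseg.differential import test_differential_segment_usage
from txseg.fixtures import simulate_usage_counts

scm, segments, design, flagged = simulate_usage_counts(
    n_genes=60, seed=11, flagged_fraction=0.25
)
res = test_differential_segment_usage(scm, segments, design)

top = res.gene_table.sort_values("pvalue").head(8)
print("gene        p-value    q-value   truly switched?")
for _, row in top.iterrows():
    mark = "yes" if row.gene_id in set(flagged) else "no"
    print(f"{row.gene_id}  {row.pvalue:9.2e}  {row.qvalue:8.2e}   {mark}")

n_hit = (res.gene_table["qvalue"] < 0.05).sum()
print(
    f"\n{len(flagged)} of {len(res.gene_table)} genes truly switched; "
    f"{n_hit} called at q<0.05."
)
print(
    "Ranking by p-value puts switched genes first; counts come straight "
    "from pseudo-alignment, with no transcript quantification step."
)
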