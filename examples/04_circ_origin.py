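"""Classify circRNA back-splice junctions by genomic origin.

A junction is exonic when both breakpoints sit on exon boundaries of
one gene, intronic when its span lies inside a single intron, and
intergenic when it overlaps no gene on its strand; the per-gene
isoform counts quantify alternative circularization.
"""

from cernakit import SimulationConfig, simulate_annotation
from cernakit.circ_annot import (
    alt_circularization, classify_origins, origin_fractions,
)

sim = SimulationConfig(seed=7, n_junctions=400)
genes, junctions, truth = simulate_annotation(sim)

calls = classify_origins(junctions, genes, slack=0)
print("origin fractions:")
print(origin_fractions(calls).round(4))
agree = sum(c.origin == truth[c.circ_id] for c in calls)
print(f"truth agreement: {agree}/{len(calls)}")

counts, frac = alt_circularization(calls, k=2)
print(f"host genes with >=2 circRNA isoforms: {frac:.2%}")
print(
    "\nThe fractions mirror the configured exonic/intronic/intergenic"
    "\nproportions; the multi-isoform fraction is the alternative-"
    "\ncircularization summary."
)
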