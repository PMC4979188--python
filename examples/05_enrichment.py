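"""Hypergeometric term enrichment of a gene set with a planted signal.

A 20-gene term is planted in a 1000-gene background; the query set of
25 genes contains 15 term members.  Printed: the enrichment table head
(k of n query genes vs K of N background genes per term).
"""

import numpy as np

from dgetag import enrich, generate_annotations

rng = np.random.default_rng(0)
genes = [f"g{i:04d}" for i in range(1000)]
members = list(rng.choice(genes, size=20, replace=False))
annotation = generate_annotations(
    genes, n_terms=40, seed=0,
    planted_term="GO:planted", planted_genes=set(members),
)
query = set(members[:15]) | set(
    rng.choice([g for g in genes if g not in members], size=10, replace=False)
)

result = enrich(query, annotation, background=set(genes), q_threshold=0.05)
print(f"query genes in background: {result.n_query}")
print(result.records.head(5).to_string(index=False))
print("\nsignificant terms (Q <= 0.05):", result.significant_terms)
# the planted term dominates: 15 of the 25 query genes carry it while
# only 20 of 1000 background genes do
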