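"""Ontology over-representation with Resnik-similarity clustering.

Hypergeometric ORA finds enriched terms (raw p < 0.1); terms are then
de-duplicated at a normalized Resnik similarity of 0.7 and grouped by
binary-cut clustering of the similarity matrix.  The layout tables behind
treemap / word-cloud / ridge displays are exported as DataFrames.
"""

import numpy as np

from bpomics import (
    binary_cut,
    display_tables,
    gen_ontology,
    ora,
    prune_redundant,
    similarity_matrix,
)

rng = np.random.default_rng(3)
focus = {f"g{i + 1:04d}" for i in rng.choice(80, size=25, replace=False)}
dag, direct = gen_ontology(25, n_genes=80, seed=3, focus_genes=focus)
universe = set(dag.annotations[dag.root])
lfc = {g: float(rng.normal(1.0 if g in focus else 0.0, 0.5)) for g in universe}

results = ora(focus, universe, dag, p_max=0.1, log2fc=lfc)
print(f"{len(results)} terms enriched at raw p < 0.1")

terms = [r.term for r in results]
sim = similarity_matrix(dag, terms)
kept = prune_redundant({r.term: r.p for r in results}, sim, threshold=0.7)
print(f"{len(kept)} terms survive redundancy pruning at similarity 0.7")

clusters = binary_cut(sim.loc[kept, kept],
                      term_p={r.term: r.p for r in results},
                      term_size={r.term: r.K for r in results})
print(f"binary cut groups them into {len(clusters.clusters)} clusters; "
      f"representatives: {clusters.representatives}")

tables = display_tables([r for r in results if r.term in set(kept)], clusters, lfc)
top = tables["ridge"].sort_values("mean_log2fc", ascending=False).head(3)
print("\ntop ridge rows (term, mean log2FC of member genes):")
for _, row in top.iterrows():
    print(f"  {row['term']}: {row['mean_log2fc']:+.2f}")
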