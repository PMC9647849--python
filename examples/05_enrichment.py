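"""Gene-set overrepresentation of a consensus DE list.

Builds a small synthetic GMT collection in which one set overlaps the DE
list heavily, then runs the one-sided Fisher exact test against the
quantified-protein universe.
"""

from tmtde import GeneSetCollection, enrich

universe = [f"GENE{i:04d}" for i in range(3000)]
collection = GeneSetCollection({
    "Mitochondrial_respiration": ("electron transport chain", frozenset(universe[:142])),
    "Synaptic_vesicle_cycle": ("", frozenset(universe[200:320])),
    "Random_set": ("", frozenset(universe[1000:1100])),
}).with_universe(universe)

# a DE list enriched for the first set: 25 of its 142 members plus noise
de_genes = set(universe[:25]) | set(universe[2000:2075])

table = enrich(de_genes, collection)
print(table[["term", "count", "ph", "percent", "pvalue", "fold_enrichment"]]
      .to_string(index=False))
# 'count' of the DE genes fall in each set of 'ph' quantified members;
# percent = 100*count/ph; the p-value is the hypergeometric upper tail.
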