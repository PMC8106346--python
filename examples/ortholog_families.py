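"""Ortholog families from bidirectional best hits, plus top-hit taxonomy.

Plants six cross-genome gene families over four genomes, recovers them as
connected components of the BBH graph, then classifies the taxonomy of
top homology hits for a hundred query genes.
"""

import itertools

from npomics.families import bidirectional_best_hits, classify_top_hits, group_families
from npomics.synth import gen_homology_tables, gen_taxonomy_hits

hits, all_genes, truth = gen_homology_tables(seed=42)
genomes = sorted({g for g, _ in all_genes})
pairs = []
for ga, gb in itertools.combinations(genomes, 2):
    pairs.extend(bidirectional_best_hits(hits[(ga, gb)], hits[(gb, ga)]))

families = group_families(pairs, all_genes)
multi = [f for f in families if len(f.members) > 1]
print(f"{len(multi)} multi-genome families (planted: {len(truth.families)})")
for f in multi:
    print(f"  {f.family_id}: {[g for _, g in f.members]}")
# Genes sharing a family are mutual best homology hits across genomes —
# the standard ortholog proxy; singletons (decoys) are not shown.

clusters, tax_hits, tax_truth = gen_taxonomy_hits(seed=42)
_, fractions = classify_top_hits(clusters, tax_hits)
print("\ntop-hit kingdom fractions:")
for kingdom, frac in fractions.items():
    if frac:
        print(f"  {kingdom:>15}: {frac:.2f}")
# The bacterial fraction estimates how often a core biosynthetic gene's
# closest non-self homolog is bacterial rather than fungal.
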