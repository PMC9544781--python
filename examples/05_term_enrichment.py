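"""Term enrichment of a gene set by the two-sided Fisher exact test.

Builds a synthetic annotation table in which one term preferentially
annotates the query set; every term with ≥ 2 annotated genes is tested
against the annotated-gene universe with BH control across terms.
"""

import numpy as np

from chronofield import AnnotationTable, fisher_enrichment

rng = np.random.default_rng(7)
genes = [f"g{i:03d}" for i in range(200)]
gene_terms = {g: {"T_background"} for g in genes}
for g in rng.choice(genes, 40, replace=False):
    gene_terms[g].add("T_random")
query = list(rng.choice(genes, 25, replace=False))
for g in query[:15]:  # T_target annotates 15 of the 25 query genes
    gene_terms[g].add("T_target")
for g in rng.choice([g for g in genes if g not in query], 10, replace=False):
    gene_terms[g].add("T_target")

result = fisher_enrichment(set(query), AnnotationTable(gene_terms))
print(result[["k11", "k21", "odds_ratio", "pvalue", "qvalue", "significant"]].round(6).to_string())
print("\nk11 = query genes with the term, k21 = background genes with it;")
print("T_target is enriched, the uniform background term is uninformative.")
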