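"""Term enrichment by the two-sided Fisher exact test with BH control.

Annotations are consumed as a plain two- or three-column table
(gene_id, term_id[, term_name]); the test universe is the set of annotated
genes (optionally intersected with a supplied background, mirroring the
practice of restricting enrichment to genes with at least one annotation).

The two-sided p-value is the exact hypergeometric tail: the sum of the
probabilities of all 2×2 tables with the observed margins whose probability
does not exceed that of the observed table. Probabilities are compared as
exact integers (binomial-coefficient weights over a common denominator), so
the p-value carries no comparison tolerance; for very large universes the
integer weights are exact Python bignums and still cheap because the
support of each table is short.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationTable:
    """gene → term annotations with an optional term-name lookup.

    The universe is every gene with ≥ 1 term; empty term sets are never
    stored.
    """

    gene_terms: dict = field(default_factory=dict)
    term_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_terms = {
            g: set(ts) for g, ts in self.gene_terms.items() if len(ts) > 0
        }

    @property
    def universe(self) -> set:
        return set(self.gene_terms)

    def term_to_genes(self) -> dict:
        out: dict = {}
        for g, ts in self.gene_terms.items():
            for t in ts:
                out.setdefault(t, set()).add(g)
        return out

    @classmethod
    def read(cls, path) -> "AnnotationTable":
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = list(table.columns)
        if len(cols) < 2:
            raise ValueError("annotation TSV needs columns gene_id, term_id[, term_name]")
        gene_terms: dict = {}
        term_names: dict = {}
        for row in table.itertuples(index=False):
            gene, term = row[0], row[1]
            gene_terms.setdefault(gene, set()).add(term)
            if len(cols) >= 3 and isinstance(row[2], str):
                term_names[term] = row[2]
        return cls(gene_terms, term_names)


def fisher_two_sided(k11: int, k12: int, k21: int, k22: int) -> float:
    """Exact two-sided Fisher p for the 2×2 table [[k11, k12], [k21, k22]].

    Enumerates the hypergeometric support with integer binomial-coefficient
    weights and sums every outcome whose weight is ≤ the observed one.
    """
    row1 = k11 + k12
    col1 = k11 + k21
    n = k11 + k12 + k21 + k22
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    weights = [comb(row1, k) * comb(n - row1, col1 - k) for k in range(lo, hi + 1)]
    observed = weights[k11 - lo]
    total = comb(n, col1)
    tail = sum(w for w in weights if w <= observed)
    return tail / total


def fisher_enrichment(
    gene_set,
    annotations: AnnotationTable,
    background=None,
    min_term_genes: int = 2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Term enrichment of a gene set against an annotation table.

    The universe is the annotated genes, intersected with ``background``
    if given; genes of ``gene_set`` outside the universe are dropped (with
    a warning recording how many). For every term with at least
    ``min_term_genes`` universe genes, the 2×2 table

        [[in-set & annotated, in-set & not], [out & annotated, out & not]]

    is tested two-sided; BH q-values are computed across the tested terms.
    The odds ratio uses a 0.5 continuity correction for display only and
    plays no role in the p-value.
    """
    universe = annotations.universe
    if background is not None:
        universe = universe & set(background)
    if not universe:
        raise ValueError("empty universe")
    selected = set(gene_set) & universe
    dropped = len(set(gene_set)) - len(selected)
    if dropped:
        warnings.warn(f"{dropped} genes outside the annotated universe dropped")
    if not selected:
        raise ValueError("gene set empty after intersecting with the universe")

    n_universe = len(universe)
    n_set = len(selected)
    rows = []
    skipped = 0
    for term, genes in sorted(annotations.term_to_genes().items()):
        in_universe = genes & universe
        if len(in_universe) < min_term_genes:
            skipped += 1
            continue
        k11 = len(in_universe & selected)
        k12 = n_set - k11
        k21 = len(in_universe) - k11
        k22 = n_universe - n_set - k21
        p = fisher_two_sided(k11, k12, k21, k22)
        odds = ((k11 + 0.5) * (k22 + 0.5)) / ((k12 + 0.5) * (k21 + 0.5))
        rows.append((term, annotations.term_names.get(term, ""), k11, k12, k21, k22, odds, p))
    if skipped:
        warnings.warn(f"{skipped} terms with fewer than {min_term_genes} universe genes skipped")
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k11", "k12", "k21", "k22", "odds_ratio", "pvalue"],
    ).set_index("term_id")
    if out.empty:
        out["qvalue"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["qvalue"] < fdr
    return out
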