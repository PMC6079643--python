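"""Fisher's exact test gene-set enrichment with Benjamini-Hochberg FDR.

Over-representation of annotation terms (GO categories, TF families,
cluster-linked sets) in a query gene set, tested one-sided against a
hypergeometric null over a declared gene universe.  Applied per expression
cluster and per sample expression domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterResult, DomainAssignment
from .matrix import SectionSeriesMatrix

__all__ = [
    "GeneSetCollection",
    "benjamini_hochberg",
    "fisher_enrichment",
    "enrich_clusters",
    "enrich_domains",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (classic FDR control)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass
class GeneSetCollection:
    """Term -> gene-set mapping restricted to a gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        restricted = {}
        for term, genes in self.sets.items():
            inside = set(genes) & self.universe
            if inside:
                restricted[term] = inside
        self.sets = restricted

    def restrict(self, universe) -> "GeneSetCollection":
        """New collection with the universe intersected down."""
        uni = set(universe) & self.universe
        return GeneSetCollection(
            {t: g for t, g in self.sets.items()}, uni, dict(self.descriptions)
        )


def fisher_enrichment(query, sets: GeneSetCollection, query_id: str = "query") -> pd.DataFrame:
    """One-sided enrichment p-values for every term, plus BH q-values.

    For a universe of N genes, a term of size K and a query of size n with k
    genes of the term, p = P(X >= k) with X ~ Hypergeom(N, K, n) — identical
    to the one-sided Fisher's exact test on the 2x2 table.  Query genes
    outside the universe are dropped with a warning.
    """
    query = set(query)
    outside = query - sets.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped: "
            f"{sorted(outside)[:5]}"
        )
        query = query & sets.universe
    if not query:
        raise ValueError("query set is empty after restriction to the universe")
    big_n = len(sets.universe)
    n = len(query)
    rows = []
    for term in sorted(sets.sets):
        term_genes = sets.sets[term]
        k = len(query & term_genes)
        big_k = len(term_genes)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term": term,
                "description": sets.descriptions.get(term, ""),
                "set_size": n,
                "term_size": big_k,
                "overlap": k,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr_q"] = benjamini_hochberg(table["p_value"])
    else:
        table["fdr_q"] = []
    table.attrs["query_id"] = query_id
    return table


def enrich_clusters(result: ClusterResult, sets: GeneSetCollection) -> dict[int, pd.DataFrame]:
    """Per-cluster enrichment tables (universe = the collection's universe)."""
    out: dict[int, pd.DataFrame] = {}
    for cluster in sorted(set(result.gene_labels.values())):
        members = [g for g, c in result.gene_labels.items() if c == cluster]
        out[cluster] = fisher_enrichment(members, sets, query_id=f"cluster_{cluster}")
    return out


def enrich_domains(
    domains: DomainAssignment,
    sets: GeneSetCollection,
    vst: SectionSeriesMatrix,
    tree: str,
) -> dict[str, pd.DataFrame]:
    """Per-sample enrichment of domain gene sets, restricted to one tree.

    Replicate series do not align section-for-section, so domain enrichment
    is computed within a single named tree.  Samples with no assigned genes
    are skipped with a notice.
    """
    tree_samples = vst.samples_of_tree(tree)  # raises KeyError on unknown tree
    out: dict[str, pd.DataFrame] = {}
    for s in tree_samples:
        query = [g for g, ss in domains.assignments.items() if s in ss]
        if not query:
            warnings.warn(f"sample {s}: no genes assigned; skipped")
            continue
        out[s] = fisher_enrichment(query, sets, query_id=f"domain_{s}")
    return out
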