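"""Network centralities and rank orders over the largest sub-network.

Four connectivity measures: degree (direct neighbours), betweenness (number
of shortest paths through a gene, unweighted and unnormalized), closeness
(reported both as total shortest-path distance, i.e. farness, and as the
standard normalized inverse), and average neighbour degree.  Betweenness and
closeness are additionally ranked from most to least central, ties sharing
the minimum rank.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import CoexpressionNetwork

__all__ = ["centralities", "rank_table", "MEASURES"]

MEASURES = ("degree", "betweenness", "closeness", "avg_neighbor_degree")


def centralities(net: CoexpressionNetwork) -> pd.DataFrame:
    """Centrality table for a connected co-expression network.

    Columns: ``degree``, ``betweenness`` (unnormalized pair counts),
    ``farness`` (total distance to all other genes), ``closeness``
    ((n-1)/farness), ``avg_neighbor_degree``, ``betweenness_rank`` and
    ``closeness_rank`` (rank 1 = most central; ties share the minimum rank).
    Edge weights (CLR scores) are ignored: paths count edges.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(g):
        raise ValueError(
            "network is disconnected; apply largest_subnetwork before computing centralities"
        )
    nodes = list(g.nodes)
    degree = pd.Series(dict(g.degree()), name="degree").loc[nodes]
    btw = pd.Series(nx.betweenness_centrality(g, normalized=False), name="betweenness").loc[nodes]
    farness = pd.Series(
        {v: sum(nx.single_source_shortest_path_length(g, v).values()) for v in nodes},
        name="farness",
    ).loc[nodes]
    n = len(nodes)
    closeness = (n - 1) / farness if n > 1 else farness * 0.0
    and_ = pd.Series(nx.average_neighbor_degree(g), name="avg_neighbor_degree").loc[nodes]

    table = pd.DataFrame(
        {
            "degree": degree.astype(int),
            "betweenness": btw,
            "farness": farness.astype(int),
            "closeness": closeness,
            "avg_neighbor_degree": and_,
        }
    )
    table["betweenness_rank"] = rankdata(-table["betweenness"], method="min").astype(int)
    table["closeness_rank"] = rankdata(-table["closeness"], method="min").astype(int)
    return table


def rank_table(table: pd.DataFrame, by: str) -> list[str]:
    """Genes in descending order of a centrality measure.

    Ties are broken by gene ID lexicographic order, so the result is
    deterministic.
    """
    if by not in MEASURES:
        raise ValueError(f"unknown measure {by!r}; choose one of {MEASURES}")
    return sorted(table.index, key=lambda g: (-table.at[g, by], g))
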