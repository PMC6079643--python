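"""Cross-species neighborhood extraction, expansion and conservation scoring.

The comparative-regulomics workflow: extract a seed gene's first-order
co-expression neighborhood, optionally expand it stepwise or subset it to
transcription factors, then ask whether the neighborhood is conserved in a
second species' network through an ortholog (gene-family) map.  The
conservation statistic — a hypergeometric overlap p-value between the
ortholog-mapped neighborhood and the candidate ortholog's neighborhood — is
this package's quantification of a readout that is qualitative in the
original analysis (presence/absence of marker genes in neighborhoods), and
reports are labeled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import CoexpressionNetwork

__all__ = [
    "OrthologMap",
    "ConservationRow",
    "neighborhood",
    "expand",
    "tf_subset",
    "conservation_test",
    "neighborhood_membership",
    "compare_species",
]


@dataclass
class OrthologMap:
    """Gene correspondences between species A and B; may be many-to-many."""

    pairs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError("ortholog pair with empty gene ID")
            if (a, b) in seen:
                raise ValueError(f"duplicate ortholog pair ({a}, {b})")
            seen.add((a, b))
        self._a_to_b: dict[str, set[str]] = {}
        self._b_to_a: dict[str, set[str]] = {}
        for a, b in self.pairs:
            self._a_to_b.setdefault(a, set()).add(b)
            self._b_to_a.setdefault(b, set()).add(a)

    def to_b(self, gene_a: str) -> set[str]:
        return set(self._a_to_b.get(gene_a, set()))

    def to_a(self, gene_b: str) -> set[str]:
        return set(self._b_to_a.get(gene_b, set()))

    def reversed(self) -> "OrthologMap":
        return OrthologMap([(b, a) for a, b in self.pairs], source=self.source)


@dataclass
class ConservationRow:
    """Conservation verdict for one seed gene (see ``conservation_test``)."""

    seed_a: str
    seed_b: str | None
    neighborhood_a: set[str]
    mapped_neighbors: set[str]
    found: set[str]
    missing: set[str]
    overlap: int
    overlap_fraction: float
    p_value: float
    verdict: str  # conserved | diverged | untestable
    note: str = ""


def _qualifying_neighbors(net: CoexpressionNetwork, gene: str, threshold: float) -> set[str]:
    g = net.graph
    return {v for v in g.neighbors(gene) if g.edges[gene, v]["clr_score"] >= threshold}


def neighborhood(net: CoexpressionNetwork, seeds, threshold: float | None = None):
    """First-order neighborhood subgraph of one or more seed genes.

    Nodes are the present seeds plus every gene linked to a seed by an edge
    with CLR >= threshold (inclusive); edge attributes (scores, signs) are
    kept.  The threshold may only be raised relative to the network's build
    threshold.  Absent seeds are reported via the graph attribute
    ``absent_seeds``; if no seed is present an error is raised.
    """
    if isinstance(seeds, str):
        seeds = [seeds]
    seeds = list(seeds)
    threshold = net.threshold if threshold is None else float(threshold)
    if threshold < net.threshold:
        raise ValueError(
            f"threshold {threshold} is below the network build threshold "
            f"{net.threshold}; re-filtering is only allowed upward"
        )
    present = [s for s in seeds if s in net.graph]
    absent = [s for s in seeds if s not in net.graph]
    if not present:
        raise ValueError(f"no seed present in the network: {seeds}")
    nodes: set[str] = set(present)
    for s in present:
        nodes |= _qualifying_neighbors(net, s, threshold)
    sub = net.graph.subgraph(nodes).copy()
    drop = [(u, v) for u, v, d in sub.edges(data=True) if d["clr_score"] < threshold]
    sub.remove_edges_from(drop)
    sub.graph["absent_seeds"] = absent
    sub.graph["seeds"] = present
    return sub


def expand(net: CoexpressionNetwork, current, threshold: float | None = None) -> set[str]:
    """One breadth step: current genes plus all their neighbors at >= threshold."""
    current = set(current)
    if not current:
        raise ValueError("cannot expand an empty gene set")
    threshold = net.threshold if threshold is None else float(threshold)
    out = set(current)
    for gene in current:
        if gene in net.graph:
            out |= _qualifying_neighbors(net, gene, threshold)
    return out


def tf_subset(genes, tf_genes) -> list[str]:
    """Subset to transcription-factor-annotated genes, order preserved."""
    tf_genes = set(tf_genes)
    return [g for g in genes if g in tf_genes]


def conservation_test(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    orthologs: OrthologMap,
    seed_a: str,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    alpha: float = 0.05,
    mode: str = "any",
) -> ConservationRow:
    """Is a seed's co-expression neighborhood conserved in species B?

    N_A is seed_a's first-order neighborhood (seed excluded) at threshold_a.
    For each ortholog of seed_a present in net_b, every n in N_A that has at
    least one B-ortholog in the network is checked for membership of the
    candidate's neighborhood at threshold_b ("any" family semantics; "best"
    uses only the first ortholog of each neighbor in map order).  Neighbors
    with no ortholog are excluded from the denominator.  Significance of the
    overlap is a hypergeometric tail with universe = net_b genes having an
    A-ortholog; the best (smallest-p) candidate is reported.  Verdict:
    "conserved" iff p <= alpha, "untestable" if no candidate or no mappable
    neighbor exists, else "diverged".  A complete overlap (every mappable
    neighbor found) also counts as conserved: on very small networks the
    hypergeometric tail cannot reach significance even for a perfect match,
    and complete presence is the strongest form of the qualitative readout.
    """
    if mode not in ("any", "best"):
        raise ValueError("mode must be 'any' or 'best'")
    if seed_a not in net_a.graph:
        raise ValueError(f"seed {seed_a!r} absent from network A")
    threshold_a = net_a.threshold if threshold_a is None else float(threshold_a)
    threshold_b = net_b.threshold if threshold_b is None else float(threshold_b)
    n_a = _qualifying_neighbors(net_a, seed_a, threshold_a)

    candidates = [b for b in sorted(orthologs.to_b(seed_a)) if b in net_b.graph]
    if not candidates:
        return ConservationRow(
            seed_a, None, n_a, set(), set(), set(), 0, float("nan"), float("nan"),
            "untestable", note="no seed ortholog present in network B",
        )

    b_nodes = set(net_b.graph.nodes)
    universe = {b for b in b_nodes if orthologs.to_a(b)}

    def map_neighbor(n: str) -> set[str]:
        orths = [b for b in sorted(orthologs.to_b(n)) if b in b_nodes]
        if not orths:
            return set()
        return set(orths) if mode == "any" else {orths[0]}

    mapped = {n: map_neighbor(n) for n in n_a}
    mappable = {n for n, orths in mapped.items() if orths}
    if not mappable:
        return ConservationRow(
            seed_a, candidates[0], n_a, set(), set(), set(), 0, float("nan"), float("nan"),
            "untestable", note="no neighborhood gene has an ortholog in network B",
        )

    best: ConservationRow | None = None
    for seed_b in candidates:
        nb_b = _qualifying_neighbors(net_b, seed_b, threshold_b)
        found = {n for n in mappable if mapped[n] & nb_b}
        k = len(found)
        n_draws = len(mappable)
        successes = len(nb_b & universe)
        p = float(hypergeom.sf(k - 1, len(universe), successes, n_draws))
        row = ConservationRow(
            seed_a=seed_a,
            seed_b=seed_b,
            neighborhood_a=n_a,
            mapped_neighbors=mappable,
            found=found,
            missing=mappable - found,
            overlap=k,
            overlap_fraction=k / n_draws,
            p_value=min(p, 1.0),
            verdict="conserved" if (p <= alpha or (k == n_draws and k > 0)) else "diverged",
            note="overlap statistic is a package-defined quantification",
        )
        if best is None or row.p_value < best.p_value:
            best = row
    return best


def neighborhood_membership(
    net: CoexpressionNetwork, seed: str, probes, threshold: float | None = None
) -> dict[str, str]:
    """Presence/absence of probe genes in a seed's neighborhood.

    Returns per probe: "present", "absent", or "absent-from-network" (the
    probe is not a node at all, distinct from a plain negative).  The seed
    itself is "present-self" by convention.
    """
    if seed not in net.graph:
        raise ValueError(f"seed {seed!r} absent from the network")
    nb = _qualifying_neighbors(net, seed, net.threshold if threshold is None else threshold)
    out: dict[str, str] = {}
    for p in probes:
        if p == seed:
            out[p] = "present-self"
        elif p not in net.graph:
            out[p] = "absent-from-network"
        else:
            out[p] = "present" if p in nb else "absent"
    return out


def compare_species(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    orthologs: OrthologMap,
    seeds_a,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    alpha: float = 0.05,
    mode: str = "any",
) -> pd.DataFrame:
    """Run ``conservation_test`` for many seeds; one report row per seed."""
    rows = []
    for seed in seeds_a:
        r = conservation_test(
            net_a, net_b, orthologs, seed, threshold_a, threshold_b, alpha, mode
        )
        rows.append(
            {
                "seed_a": r.seed_a,
                "seed_b": r.seed_b,
                "n_neighbors_a": len(r.neighborhood_a),
                "n_mapped": len(r.mapped_neighbors),
                "overlap": r.overlap,
                "overlap_fraction": r.overlap_fraction,
                "p_value": r.p_value,
                "verdict": r.verdict,
            }
        )
    return pd.DataFrame(rows)
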