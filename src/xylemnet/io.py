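"""File formats: expression TSV, GMT gene sets, ortholog TSV, edge lists,
GraphML, annotation tables and JSON reports.

The expression TSV dialect is a UTF-8 table whose header row is
``gene_id<TAB>T1:01<TAB>T1:02...`` — each sample column named by replicate
tree and section position — followed by one numeric row per gene.  All
writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .comparative import OrthologMap
from .enrichment import GeneSetCollection
from .matrix import SectionSeriesMatrix
from .network import CLRMatrix, CoexpressionNetwork

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_orthologs",
    "write_orthologs",
    "read_annotation",
    "write_annotation",
    "write_network",
    "read_network",
    "write_graphml",
    "write_report",
]


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


def _parse_sample_header(name: str, lineno: int = 1) -> tuple[str, int]:
    try:
        tree, pos = name.split(":")
        return tree, int(pos)
    except ValueError as exc:
        raise ParseError(
            f"line {lineno}: sample header {name!r} is not of the form TREE:POSITION"
        ) from exc


def read_expression_tsv(path, value_kind: str = "counts") -> SectionSeriesMatrix:
    """Read a gene x sample expression TSV with tree:position sample headers."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "gene_id":
            raise ParseError(f"{path} line 1: first header field must be 'gene_id', got {cols[0]!r}")
        sample_ids = cols[1:]
        if not sample_ids:
            raise ParseError(f"{path} line 1: no sample columns")
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path} line 1: duplicate sample headers")
        meta_rows = [_parse_sample_header(s) for s in sample_ids]
        genes: list[str] = []
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path} line {lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                data.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-numeric cell") from exc
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene IDs {dups[:5]}")
    values = pd.DataFrame(data, index=genes, columns=sample_ids)
    if value_kind == "counts" and np.allclose(values.to_numpy() % 1, 0):
        values = values.astype(np.int64)
    meta = pd.DataFrame(meta_rows, index=sample_ids, columns=["tree", "position"])
    return SectionSeriesMatrix(values, meta, value_kind)


def write_expression_tsv(matrix: SectionSeriesMatrix, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy()
        integral = np.issubdtype(arr.dtype, np.integer)
        for gene, row in zip(matrix.gene_ids, arr):
            if integral:
                cells = [str(int(v)) for v in row]
            else:
                cells = [format(float(v), ".10g") for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


# -- gene sets (GMT) ---------------------------------------------------------


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read the standard GMT dialect: term <TAB> description <TAB> gene...

    If ``universe`` is None, the union of all set members is used.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path} line {lineno}: GMT lines need term, description and >= 1 gene"
                )
            term = fields[0]
            if term in sets:
                raise ParseError(f"{path} line {lineno}: duplicate term {term!r}")
            sets[term] = set(fields[2:])
            descriptions[term] = fields[1]
    uni = set(universe) if universe is not None else set().union(*sets.values())
    return GeneSetCollection(sets, uni, descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(sets.sets):
            desc = sets.descriptions.get(term, "")
            fh.write("\t".join([term, desc] + sorted(sets.sets[term])) + "\n")


# -- orthologs ---------------------------------------------------------------


def read_orthologs(path) -> OrthologMap:
    """Read an ortholog TSV: gene_a <TAB> gene_b [<TAB> family_id]."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path} line {lineno}: need at least gene_a and gene_b")
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs, source=str(path))


def write_orthologs(orthologs: OrthologMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in orthologs.pairs:
            fh.write(f"{a}\t{b}\n")


# -- gene annotation ---------------------------------------------------------


def write_annotation(path, tf_genes, cluster_label=None) -> None:
    """Write gene annotation TSV: gene_id, is_tf, cluster."""
    cluster_label = cluster_label or {}
    genes = sorted(set(tf_genes) | set(cluster_label))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tis_tf\tcluster\n")
        for g in genes:
            fh.write(f"{g}\t{int(g in set(tf_genes))}\t{cluster_label.get(g, '')}\n")


def read_annotation(path) -> tuple[set[str], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    tf = {r.gene_id for r in df.itertuples() if r.is_tf == "1"}
    clusters = {r.gene_id: r.cluster for r in df.itertuples() if r.cluster}
    return tf, clusters


# -- networks ----------------------------------------------------------------


def write_network(net: CoexpressionNetwork, path) -> None:
    """Edge-list TSV: gene1, gene2, clr_score, pearson_r, sign (full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# threshold={net.threshold!r}\n")
        fh.write("gene1\tgene2\tclr_score\tpearson_r\tsign\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['clr_score']!r}\t{d['pearson_r']!r}\t{d['sign']}\n")
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
        for n in isolated:
            fh.write(f"{n}\t\t\t\t\n")


def read_network(path) -> CoexpressionNetwork:
    path = Path(path)
    g = nx.Graph()
    threshold = 0.0
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("# threshold="):
            threshold = float(first.split("=", 1)[1])
            header = fh.readline().rstrip("\n")
        else:
            header = first
        if header.split("\t")[:2] != ["gene1", "gene2"]:
            raise ParseError(f"{path}: not an edge-list TSV")
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise ParseError(f"{path} line {lineno}: expected 5 fields")
            if f[1] == "":
                g.add_node(f[0])
                continue
            g.add_edge(
                f[0], f[1],
                clr_score=float(f[2]), pearson_r=float(f[3]), sign=f[4],
                zero_r=(float(f[3]) == 0.0),
            )
    return CoexpressionNetwork(g, threshold)


def write_graphml(net: CoexpressionNetwork, path, centrality_table: pd.DataFrame | None = None):
    """GraphML export; nodes optionally carry centralities as attributes."""
    g = net.graph.copy()
    if centrality_table is not None:
        for gene in g.nodes:
            if gene in centrality_table.index:
                for col in centrality_table.columns:
                    g.nodes[gene][col] = float(centrality_table.at[gene, col])
    for _, _, d in g.edges(data=True):
        d.pop("zero_r", None)  # GraphML-friendly scalar attrs only
    nx.write_graphml(g, path)


def write_report(obj, path) -> None:
    """JSON report writer (sets become sorted lists)."""

    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
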