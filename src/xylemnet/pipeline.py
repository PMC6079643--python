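"""End-to-end pipeline: counts -> VST -> network -> topology -> clusters ->
domains -> enrichment, with every stage's outputs and parameters logged to a
run directory.  Identical config + inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import assign_expression_domain, cluster_genes, variance_filter
from .config import PipelineConfig
from .enrichment import GeneSetCollection, enrich_clusters, enrich_domains
from .io import write_expression_tsv, write_network, write_report
from .matrix import SectionSeriesMatrix
from .network import (
    build_network,
    clr_transform,
    largest_subnetwork,
    mutual_information,
    select_threshold_scale_free,
)
from .preprocess import PreprocessConfig, compute_size_factors, filter_expressed, vst_transform
from .topology import centralities

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    counts: SectionSeriesMatrix,
    out_dir,
    gene_sets: GeneSetCollection | None = None,
) -> Path:
    """Run every analysis stage on a count matrix and write a run directory.

    Returns the run directory path.  The directory contains per-stage TSVs
    plus ``run_log.json`` with the parameters, seed and the row/edge counts
    of every stage — enough to reconstruct every number in the outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"package_version": __version__, "config": config.to_dict(), "stages": {}}

    stage = "preprocess"
    try:
        pre_cfg = PreprocessConfig(
            vst_threshold=config.vst_threshold,
            min_samples_per_tree=config.min_samples_per_tree,
            min_trees=config.min_trees,
            dispersion_floor=config.dispersion_floor,
        )
        size_factors = compute_size_factors(counts)
        vst = vst_transform(counts, size_factors, dispersion_floor=config.dispersion_floor)
        expressed = filter_expressed(vst, pre_cfg)
        if not expressed:
            raise ValueError("no gene passes the expression filter")
        vst_expr = vst.subset_genes(expressed)
        size_factors.to_csv(out / "size_factors.tsv", sep="\t", header=True)
        write_expression_tsv(vst_expr, out / "vst_expressed.tsv")
        log["stages"][stage] = {
            "n_genes_in": counts.n_genes,
            "n_samples": counts.n_samples,
            "n_expressed": len(expressed),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "network"
    try:
        mi = mutual_information(vst_expr, bins=config.mi_bins, scheme=config.mi_scheme)
        clr = clr_transform(mi)
        if config.scan_candidates is not None:
            threshold, report = select_threshold_scale_free(clr, config.scan_candidates)
            report.table.to_csv(out / "threshold_scan.tsv", sep="\t", index=False)
        else:
            threshold = config.clr_threshold
        net = build_network(vst_expr, clr, threshold)
        write_network(net, out / "network_edges.tsv")
        log["stages"][stage] = {
            "mi_bins": mi.bins,
            "mi_scheme": mi.scheme,
            "threshold": threshold,
            "n_edges": net.n_edges,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "topology"
    try:
        sub = largest_subnetwork(net)
        table = centralities(sub)
        table.to_csv(out / "centralities.tsv", sep="\t", index_label="gene")
        log["stages"][stage] = {
            "largest_component_genes": sub.graph.number_of_nodes(),
            "largest_component_edges": sub.n_edges,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "clustering"
    try:
        filtered = variance_filter(vst_expr, config.min_sigma, config.sigma_statistic)
        k = min(config.n_clusters, len(filtered))
        if k < 1:
            raise ValueError("no gene passes the variance filter")
        result = cluster_genes(vst_expr, filtered, k)
        pd.Series(result.gene_labels, name="cluster").to_csv(
            out / "gene_clusters.tsv", sep="\t", index_label="gene"
        )
        domains = assign_expression_domain(vst_expr, config.domain_tolerance)
        with open(out / "expression_domains.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tsamples\n")
            for g in vst_expr.gene_ids:
                if g in domains.assignments:
                    fh.write(g + "\t" + ",".join(sorted(domains.assignments[g])) + "\n")
        log["stages"][stage] = {
            "n_variance_filtered": len(filtered),
            "k": k,
            "n_domain_genes": len(domains.assignments),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "enrichment"
    if gene_sets is not None:
        try:
            sets = gene_sets.restrict(expressed)
            cluster_tables = enrich_clusters(result, sets)
            frames = []
            for cluster, tbl in cluster_tables.items():
                tbl = tbl.copy()
                tbl.insert(0, "cluster", cluster)
                frames.append(tbl)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "cluster_enrichment.tsv", sep="\t", index=False
            )
            tree = config.enrichment_tree
            if tree in vst_expr.trees:
                domain_tables = enrich_domains(domains, sets, vst_expr, tree)
                frames = []
                for sample, tbl in domain_tables.items():
                    tbl = tbl.copy()
                    tbl.insert(0, "sample", sample)
                    frames.append(tbl)
                if frames:
                    pd.concat(frames, ignore_index=True).to_csv(
                        out / "domain_enrichment.tsv", sep="\t", index=False
                    )
            log["stages"][stage] = {
                "n_terms": len(sets.sets),
                "n_cluster_tables": len(cluster_tables),
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    write_report(log, out / "run_log.json")
    return out
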