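"""Count normalization, variance stabilization, expression filter, imputation.

The entry point of the analysis: raw section-series counts are normalized by
median-of-ratios size factors, variance-stabilized with the closed-form
negative-binomial transform, filtered for expression (VST > threshold in at
least ``min_samples_per_tree`` sections of at least ``min_trees`` replicate
trees), and missing sections are imputed as the mean of their two flanking
sections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import SectionSeriesMatrix, sample_id

__all__ = [
    "PreprocessConfig",
    "compute_size_factors",
    "vst_transform",
    "estimate_dispersion",
    "filter_expressed",
    "impute_missing_sample",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Constants of the expression filter and VST.

    ``vst_threshold=3``, ``min_samples_per_tree=2`` and ``min_trees=2``
    implement the rule "VST above 3 in two samples per tree in at least two
    replicate trees".
    """

    vst_threshold: float = 3.0
    min_samples_per_tree: int = 2
    min_trees: int = 2
    dispersion_floor: float = 1e-6
    allow_pseudo_fallback: bool = False

    def validate(self, n_trees: int | None = None) -> None:
        if self.vst_threshold <= 0:
            raise ValueError("vst_threshold must be positive")
        if self.min_samples_per_tree < 1:
            raise ValueError("min_samples_per_tree must be >= 1")
        if self.min_trees < 1:
            raise ValueError("min_trees must be >= 1")
        if self.dispersion_floor <= 0:
            raise ValueError("dispersion_floor must be positive")
        if n_trees is not None and self.min_trees > n_trees:
            raise ValueError(f"min_trees={self.min_trees} exceeds number of trees ({n_trees})")


class NoUsableGeneError(ValueError):
    """No gene row is free of zeros, so median-of-ratios is undefined.

    Either drop all-zero-containing genes upstream or enable the pseudo-count
    fallback (log-mean over positive entries) explicitly via
    ``allow_pseudo_fallback``.
    """


def compute_size_factors(
    counts: SectionSeriesMatrix, allow_pseudo_fallback: bool = False
) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each sample s, the factor is the median over usable genes of
    ``counts[g, s] / geometric_mean_g`` where usable genes are rows with no
    zero entry (the geometric mean is undefined at zero).
    """
    if counts.value_kind != "counts":
        raise ValueError("size factors are defined on a counts matrix")
    arr = counts.values.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if usable.any():
        logc = np.log(arr[usable])
        log_geo = logc.mean(axis=1)
        ratios = logc - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    elif allow_pseudo_fallback:
        # fallback: per-gene log-mean over positive entries only
        logc = np.full_like(arr, np.nan, dtype=float)
        np.log(arr, out=logc, where=arr > 0)
        log_geo = np.nanmean(logc, axis=1)
        keep = np.isfinite(log_geo)
        if not keep.any():
            raise NoUsableGeneError("matrix has no positive entries at all")
        ratios = logc[keep] - log_geo[keep, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise NoUsableGeneError(
            "no gene has all-positive counts; median-of-ratios undefined. "
            "Enable allow_pseudo_fallback to use the log-mean-over-positive-entries "
            "fallback explicitly."
        )
    if not np.all(factors > 0):
        raise ValueError("computed size factors are not all positive")
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def estimate_dispersion(
    counts: SectionSeriesMatrix, size_factors: pd.Series, floor: float = 1e-6
) -> float:
    """Pooled NB dispersion by method of moments on normalized counts.

    alpha_g = max(0, (s_g^2 - m_g) / m_g^2) per gene; the estimate is the
    median over genes with positive mean, floored at ``floor``.
    """
    norm = counts.values.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    m = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    ok = m > 0
    if not ok.any():
        warnings.warn("all-zero matrix: dispersion set to floor")
        return floor
    alpha_g = np.maximum(0.0, (s2[ok] - m[ok]) / m[ok] ** 2)
    alpha = float(np.median(alpha_g))
    if alpha <= 0:
        warnings.warn("moment dispersion estimate <= 0 everywhere; using floor")
        return floor
    return max(alpha, floor)


def vst_transform(
    counts: SectionSeriesMatrix,
    size_factors: pd.Series,
    dispersion: float | None = None,
    dispersion_floor: float = 1e-6,
) -> SectionSeriesMatrix:
    """Closed-form NB variance-stabilizing transform.

    ``t(n) = (2/ln 2) * asinh(sqrt(alpha * n / sf))`` — the variance
    stabilizer for a negative binomial with variance ``mu + alpha*mu^2``,
    scaled so that for large counts differences behave as log2 fold changes.
    Strictly increasing in n with t(0) = 0.
    """
    if counts.value_kind != "counts":
        raise ValueError("vst_transform expects a counts matrix")
    sf = size_factors.reindex(counts.values.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, sf, floor=dispersion_floor)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    norm = counts.values.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    vst = (2.0 / np.log(2.0)) * np.arcsinh(np.sqrt(dispersion * norm))
    values = pd.DataFrame(vst, index=counts.values.index, columns=counts.values.columns)
    return SectionSeriesMatrix(values, counts.sample_meta.copy(), "vst")


def filter_expressed(vst: SectionSeriesMatrix, cfg: PreprocessConfig | None = None) -> list[str]:
    """Genes expressed above threshold in enough sections of enough trees.

    A gene is kept iff the number of trees with at least
    ``min_samples_per_tree`` sections exceeding ``vst_threshold`` (strictly)
    is at least ``min_trees``.  Returns kept gene IDs in input order.
    """
    cfg = cfg or PreprocessConfig()
    if vst.value_kind != "vst":
        raise ValueError("filter_expressed expects a VST matrix")
    trees = vst.trees
    cfg.validate(n_trees=len(trees))
    for tree in trees:
        if len(vst.samples_of_tree(tree)) < cfg.min_samples_per_tree:
            raise ValueError(
                f"tree {tree} has fewer than min_samples_per_tree="
                f"{cfg.min_samples_per_tree} samples; filter undefined"
            )
    arr = vst.values.to_numpy()
    tree_ok = np.zeros(vst.n_genes, dtype=int)
    for tree in trees:
        cols = [vst.sample_ids.index(s) for s in vst.samples_of_tree(tree)]
        n_above = (arr[:, cols] > cfg.vst_threshold).sum(axis=1)
        tree_ok += n_above >= cfg.min_samples_per_tree
    keep = tree_ok >= cfg.min_trees
    return [g for g, k in zip(vst.gene_ids, keep) if k]


def impute_missing_sample(
    matrix: SectionSeriesMatrix, tree: str, position: int
) -> SectionSeriesMatrix:
    """Insert a missing section as the mean of its two flanking sections.

    Both flanking positions (position-1 and position+1) must exist within the
    same tree; there is no defined rule for a missing sample at a series end.
    """
    sid = sample_id(tree, position)
    if sid in matrix.values.columns:
        raise ValueError(f"sample {sid} already present")
    left, right = sample_id(tree, position - 1), sample_id(tree, position + 1)
    for flank in (left, right):
        if flank not in matrix.values.columns:
            raise ValueError(
                f"cannot impute {sid}: flanking sample {flank} missing "
                "(no rule is defined for a missing sample at a series end)"
            )
    new_col = (matrix.values[left] + matrix.values[right]) / 2.0
    values = matrix.values.copy()
    meta = matrix.sample_meta.copy()
    # insert directly after the left flank to keep positions increasing
    insert_at = list(values.columns).index(left) + 1
    values.insert(insert_at, sid, new_col)
    meta_new = pd.DataFrame({"tree": [tree], "position": [position]}, index=[sid])
    meta = pd.concat([meta.iloc[:insert_at], meta_new, meta.iloc[insert_at:]])
    # mean of integer counts may be fractional; a counts matrix only requires
    # non-negative finite values, so the kind is preserved either way
    return SectionSeriesMatrix(values, meta, matrix.value_kind)
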