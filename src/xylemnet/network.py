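"""Signed MI/CLR co-expression network inference.

Pairwise dependency between expression profiles is measured with mutual
information (MI, in nats) on discretized profiles; the context likelihood of
relatedness (CLR) converts each MI value into a background-corrected Z-score
against the score distributions of the two genes involved; the edge threshold
is chosen by a scale-freeness scan (goodness of the power-law fit to the
log-binned degree distribution); edges of the thresholded graph are signed by
the Pearson correlation of the VST profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .matrix import SectionSeriesMatrix

__all__ = [
    "MIMatrix",
    "CLRMatrix",
    "CoexpressionNetwork",
    "ThresholdReport",
    "mutual_information",
    "clr_transform",
    "select_threshold_scale_free",
    "build_network",
    "largest_subnetwork",
]


@dataclass
class MIMatrix:
    """Symmetric pairwise mutual information (nats); diagonal is NaN."""

    gene_ids: list[str]
    values: np.ndarray
    bins: int
    scheme: str
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        off = ~np.eye(len(self.gene_ids), dtype=bool)
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("MI matrix must be symmetric")
        if not np.all(np.isfinite(self.values[off])):
            raise ValueError("off-diagonal MI entries must be finite")
        if (self.values[off] < -1e-12).any():
            raise ValueError("MI entries must be non-negative")


@dataclass
class CLRMatrix:
    """Background-corrected pairwise Z-scores; symmetric, non-negative, zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("CLR matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("CLR entries must be non-negative")


@dataclass
class CoexpressionNetwork:
    """Undirected co-expression graph.

    Edges carry ``clr_score`` (>= threshold), ``pearson_r`` and ``sign``
    ('+'/'-').  All genes are present as nodes, including isolated ones.
    """

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# discretization


def _equal_frequency_labels(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based bin labels: bin = ordinal_rank * bins // n.

    Ties are broken by sample order (stable sort), so any strictly monotone
    transform of x yields identical labels.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return ranks * bins // n


def _equal_width_labels(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=np.int64)
    lab = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.minimum(lab, bins - 1)


def _bspline_weights(x: np.ndarray, bins: int, order: int = 3) -> np.ndarray:
    """Spline-weighted soft binning (order-3 B-spline basis, clamped knots).

    Each sample receives a weight vector over the ``bins`` basis functions
    (rows sum to 1), generalizing hard histograms to fractional membership.
    """
    degree = order - 1
    if bins < order:
        raise ValueError(f"bspline scheme needs bins >= {order}")
    lo, hi = x.min(), x.max()
    z = np.zeros_like(x, dtype=float) if hi == lo else (x - lo) / (hi - lo)
    n_internal = bins - order
    t = np.concatenate(
        [np.zeros(order), np.linspace(0, 1, n_internal + 2)[1:-1], np.ones(order)]
    )
    w = BSpline.design_matrix(z, t, degree, extrapolate=False).toarray()
    return w


def _entropy(p: np.ndarray, axis=None) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=axis)


def mutual_information(
    matrix: SectionSeriesMatrix, bins: int | None = None, scheme: str = "equal_frequency"
) -> MIMatrix:
    """All-pairs mutual information between gene expression profiles.

    MI is computed in nats from the discretized joint distribution,
    ``MI = sum p(a,b) ln[p(a,b)/(p(a)p(b))]``.  The default bin count is
    ``floor(sqrt(n_samples))`` (7 bins at 51 samples).  ``equal_frequency``
    (rank-based) is the default scheme; ``equal_width`` and the order-3
    ``bspline`` soft-binning estimator are available.

    Constant gene profiles get MI 0 against all partners and are listed in
    ``constant_genes``.
    """
    arr = matrix.values.to_numpy(dtype=float)
    genes = matrix.gene_ids
    n_genes, n_samples = arr.shape
    if n_samples < 8:
        raise ValueError(f"need at least 8 samples, got {n_samples}")
    if bins is None:
        bins = max(2, int(np.floor(np.sqrt(n_samples))))
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if bins > n_samples:
        raise ValueError(f"bins={bins} exceeds number of samples ({n_samples})")
    if scheme not in ("equal_frequency", "equal_width", "bspline"):
        raise ValueError(f"unknown binning scheme {scheme!r}")

    constant = [g for g, row in zip(genes, arr) if np.ptp(row) == 0]

    if scheme == "bspline":
        W = np.stack([_bspline_weights(row, bins) for row in arr])  # (G, S, B)
        marg = W.sum(axis=1) / n_samples  # (G, B)
        h_marg = _entropy(marg, axis=1)  # (G,)
        mi = np.zeros((n_genes, n_genes))
        for i in range(n_genes):
            joint = np.einsum("sa,gsb->gab", W[i], W) / n_samples
            h_joint = _entropy(joint, axis=(1, 2))
            mi[i] = h_marg[i] + h_marg - h_joint
    else:
        labeler = _equal_frequency_labels if scheme == "equal_frequency" else _equal_width_labels
        labels = np.stack([labeler(row, bins) for row in arr])  # (G, S)
        counts_marg = np.stack(
            [np.bincount(lab, minlength=bins) for lab in labels]
        )  # (G, B)
        h_marg = _entropy(counts_marg / n_samples, axis=1)
        mi = np.zeros((n_genes, n_genes))
        for i in range(n_genes):
            codes = labels[i][None, :] * bins + labels  # (G, S)
            offs = np.arange(n_genes)[:, None] * (bins * bins) + codes
            joint = np.bincount(offs.ravel(), minlength=n_genes * bins * bins).reshape(
                n_genes, bins, bins
            )
            h_joint = _entropy(joint / n_samples, axis=(1, 2))
            mi[i] = h_marg[i] + h_marg - h_joint

    mi = np.maximum(0.0, (mi + mi.T) / 2.0)  # enforce exact symmetry, clip fp negatives
    const_idx = [genes.index(g) for g in constant]
    mi[const_idx, :] = 0.0
    mi[:, const_idx] = 0.0
    np.fill_diagonal(mi, np.nan)
    return MIMatrix(list(genes), mi, bins, scheme, constant)


# ---------------------------------------------------------------------------
# CLR


def clr_transform(mi: MIMatrix) -> CLRMatrix:
    """Context-likelihood-of-relatedness background correction.

    For each gene i, mu_i and sigma_i are the mean and population SD of its
    off-diagonal MI values; ``z_i(j) = max(0, (MI(i,j) - mu_i)/sigma_i)`` and
    ``CLR(i,j) = sqrt(z_i(j)^2 + z_j(i)^2)`` (the rectified "mixed" CLR).
    A gene with sigma_i = 0 contributes z = 0.
    """
    n = len(mi.gene_ids)
    if n < 3:
        raise ValueError("CLR background is undefined for fewer than 3 genes")
    m = mi.values.copy()
    off = ~np.eye(n, dtype=bool)
    mu = np.nanmean(np.where(off, m, np.nan), axis=1)
    sigma = np.nanstd(np.where(off, m, np.nan), axis=1)  # population SD
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - mu[:, None]) / sigma[:, None]
    z = np.where(sigma[:, None] > 0, z, 0.0)
    z = np.maximum(0.0, np.nan_to_num(z, nan=0.0))
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    return CLRMatrix(list(mi.gene_ids), clr)


# ---------------------------------------------------------------------------
# scale-free threshold selection


@dataclass
class ThresholdReport:
    """Per-candidate scale-freeness fit: (threshold, n_edges, gamma, r2)."""

    table: pd.DataFrame
    selected: float


def _log_binned_powerlaw_fit(degrees: np.ndarray) -> tuple[float, float]:
    """Fit ln P(k) = a - gamma ln k on logarithmically binned degrees.

    Returns (gamma, R^2).  Bins are powers of two [2^j, 2^(j+1)); only bins
    with at least one count enter the regression.  With fewer than 3 occupied
    bins a line is unconstrained (2 points always fit exactly), so the fit is
    reported undefined as (nan, -inf).
    """
    kmax = degrees.max()
    n_bins = int(np.floor(np.log2(kmax))) + 1
    edges = 2.0 ** np.arange(n_bins + 1)  # [1,2), [2,4), ...
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])  # geometric bin centers
    occupied = counts > 0
    if occupied.sum() < 3:
        return float("nan"), float("-inf")
    density = counts[occupied] / widths[occupied] / degrees.size
    x = np.log(centers[occupied])
    y = np.log(density)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), float(r2)


def select_threshold_scale_free(
    clr: CLRMatrix, candidates, min_edges: int = 30
) -> tuple[float, ThresholdReport]:
    """Choose the CLR edge threshold maximizing scale-freeness.

    For each candidate the thresholded graph's degree distribution (isolated
    nodes excluded) is log-binned and fit to a power law; the candidate with
    the highest R^2 wins, ties going to the smallest threshold.  Candidates
    yielding fewer than ``min_edges`` edges are reported but ineligible.
    """
    candidates = sorted(float(c) for c in candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate threshold")
    n = len(clr.gene_ids)
    iu = np.triu_indices(n, k=1)
    scores = clr.values[iu]
    rows = []
    for theta in candidates:
        mask = scores >= theta
        n_edges = int(mask.sum())
        if n_edges == 0:
            rows.append({"threshold": theta, "n_edges": 0, "gamma": np.nan, "r2": np.nan})
            continue
        deg = np.zeros(n, dtype=np.int64)
        np.add.at(deg, iu[0][mask], 1)
        np.add.at(deg, iu[1][mask], 1)
        gamma, r2 = _log_binned_powerlaw_fit(deg[deg > 0])
        rows.append(
            {
                "threshold": theta,
                "n_edges": n_edges,
                "gamma": gamma,
                "r2": r2 if np.isfinite(r2) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    eligible = table[(table["n_edges"] >= min_edges) & table["r2"].notna()]
    if eligible.empty:
        raise ValueError(
            "no candidate threshold yields at least "
            f"{min_edges} edges with a defined fit; edge counts: "
            + ", ".join(f"{r.threshold}:{r.n_edges}" for r in table.itertuples())
        )
    best_r2 = eligible["r2"].max()
    # ties (bitwise-equal R^2) break toward the smallest threshold
    selected = float(eligible.loc[eligible["r2"] == best_r2, "threshold"].iloc[0])
    return selected, ThresholdReport(table, selected)


# ---------------------------------------------------------------------------
# thresholded signed network


def build_network(
    vst: SectionSeriesMatrix, clr: CLRMatrix, threshold: float
) -> CoexpressionNetwork:
    """Link every gene pair with CLR >= threshold; sign edges by Pearson r.

    Pearson correlation is computed on the VST profiles over all samples of
    all trees concatenated in sampling order.  r = 0 (including a constant
    profile) is assigned sign '+' and flagged via the ``zero_r`` edge
    attribute.
    """
    if list(vst.gene_ids) != list(clr.gene_ids):
        a, b = set(vst.gene_ids), set(clr.gene_ids)
        raise ValueError(
            f"gene IDs differ between VST matrix and CLR matrix; "
            f"only in VST: {sorted(a - b)[:5]}, only in CLR: {sorted(b - a)[:5]}"
        )
    genes = list(clr.gene_ids)
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    mask = clr.values[iu] >= threshold
    arr = vst.values.to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = iu[0][mask], iu[1][mask]
    if ii.size:
        centered = arr - arr.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        for i, j in zip(ii, jj):
            denom = norms[i] * norms[j]
            r = float(centered[i] @ centered[j] / denom) if denom > 0 else 0.0
            r = float(np.clip(r, -1.0, 1.0))
            g.add_edge(
                genes[i],
                genes[j],
                clr_score=float(clr.values[i, j]),
                pearson_r=r,
                sign="-" if r < 0 else "+",
                zero_r=(r == 0.0),
            )
    return CoexpressionNetwork(g, float(threshold))


def largest_subnetwork(net: CoexpressionNetwork) -> CoexpressionNetwork:
    """Node-induced subgraph of the largest connected component.

    Isolated nodes never qualify; size ties break toward the component
    containing the lexicographically smallest gene ID.
    """
    components = [c for c in nx.connected_components(net.graph) if len(c) > 1]
    if not components:
        raise ValueError("network has no edges; largest sub-network undefined")
    best = min(components, key=lambda c: (-len(c), min(c)))
    sub = net.graph.subgraph(best).copy()
    return CoexpressionNetwork(sub, net.threshold)
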