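"""Synthetic cryosection-series expression data with planted structure.

Emulates the sampling design of the wood-development study this package
re-implements: three replicate trees, each contributing 14-18 pooled
tangential sections spanning the developmental axis from cambium to mature
xylem.  Genes belong to clusters with Gaussian expression peaks at
cluster-specific positions along the axis, a configurable fraction of
profile-less noise genes mimics the "no defined profile" pool, counts are
negative-binomial with a single global dispersion, and per-sample library
sizes vary log-normally.

A second generator plants regulatory modules (seed hubs with co-varying
target sets) in two pseudo-species linked by a one-to-one ortholog map, with
a configurable number of hubs whose targets are rewired in species B.  This
is the ground truth for the cross-species conservation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import SectionSeriesMatrix, sample_id

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_series", "simulate_species_pair"]

NOISE_LABEL = "z"
_CLUSTER_LETTERS = "abcdefghijklmnopqrstuvwxy"


class ParameterError(ValueError):
    """A configuration field is outside its valid range."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic section-series generator.

    Defaults mirror the study design being emulated: 6 real clusters plus a
    noise pool, 3 replicate trees with 14-18 sections each, negative-binomial
    counts with variance mu + alpha*mu^2.
    """

    n_genes: int = 600
    n_clusters: int = 6
    n_trees: int = 3
    samples_per_tree: list[int] | None = None  # None: drawn uniformly from 14-18
    peak_positions: list[float] | None = None  # None: evenly spaced in (0, 1)
    peak_width: float = 0.1
    expression_base: float = 50.0
    amplitude: float = 400.0  # 8 x expression_base
    nb_dispersion: float = 0.1
    noise_gene_fraction: float = 0.2
    tf_fraction: float = 0.08
    n_terms: int = 3  # gene sets planted per cluster
    library_size_cv: float = 0.2
    rng_seed: int = 0
    missing_sample: tuple[str, int] | None = None  # (tree, position) column to blank

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be a positive integer")
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be a positive integer")
        if self.n_clusters > len(_CLUSTER_LETTERS):
            raise ParameterError(f"n_clusters must be <= {len(_CLUSTER_LETTERS)}")
        if self.n_trees < 1:
            raise ParameterError("n_trees must be a positive integer")
        if self.samples_per_tree is not None:
            if len(self.samples_per_tree) != self.n_trees:
                raise ParameterError("samples_per_tree length must equal n_trees")
            if any(s < 2 for s in self.samples_per_tree):
                raise ParameterError("samples_per_tree entries must be >= 2")
        if self.peak_positions is not None:
            if len(self.peak_positions) != self.n_clusters:
                raise ParameterError("peak_positions length must equal n_clusters")
            if any(not (0.0 < p < 1.0) for p in self.peak_positions):
                raise ParameterError("peak_positions must lie strictly within (0, 1)")
        if self.peak_width <= 0:
            raise ParameterError("peak_width must be positive")
        if self.expression_base <= 0:
            raise ParameterError("expression_base must be positive")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be non-negative")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be non-negative")
        if not 0.0 <= self.noise_gene_fraction <= 1.0:
            raise ParameterError("noise_gene_fraction must be in [0, 1]")
        if not 0.0 <= self.tf_fraction <= 1.0:
            raise ParameterError("tf_fraction must be in [0, 1]")
        if self.n_terms < 0:
            raise ParameterError("n_terms must be >= 0")
        if self.library_size_cv < 0:
            raise ParameterError("library_size_cv must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated matrix pair.

    ``cluster_label`` maps every gene to its cluster letter ('z' marks the
    profile-less noise pool).  ``module_edges`` are gene pairs that truly
    co-vary.  For the two-species generator, ``seed_targets_a/_b`` give each
    hub's true target set per species, ``diverged_seeds`` the hubs rewired in
    species B, and ``orthologs`` the planted A<->B gene pairs.
    """

    cluster_label: dict[str, str]
    module_edges: list[tuple[str, str]] = field(default_factory=list)
    tf_genes: set[str] = field(default_factory=set)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    seed_targets_a: dict[str, set[str]] = field(default_factory=dict)
    seed_targets_b: dict[str, set[str]] = field(default_factory=dict)
    diverged_seeds: set[str] = field(default_factory=set)
    orthologs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.diverged_seeds) <= set(self.seed_targets_a) | set(self.cluster_label):
            raise ValueError("diverged_seeds must be a subset of the seed hubs")


# ---------------------------------------------------------------------------


def _axis_positions(samples_per_tree: list[int]) -> list[np.ndarray]:
    """Developmental-axis coordinate of each section: rank/(n_sections-1) per tree.

    Trees with different section counts yield slightly offset grids, mirroring
    replicate series that do not align sample-for-sample.
    """
    return [np.arange(n) / (n - 1) for n in samples_per_tree]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0.0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def _sample_design(cfg: SimulationConfig, rng: np.random.Generator):
    if cfg.samples_per_tree is None:
        samples_per_tree = [int(rng.integers(14, 19)) for _ in range(cfg.n_trees)]
    else:
        samples_per_tree = list(cfg.samples_per_tree)
    trees = [f"T{i + 1}" for i in range(cfg.n_trees)]
    sample_ids: list[str] = []
    meta_rows = []
    xs: list[float] = []
    for tree, n, axis in zip(trees, samples_per_tree, _axis_positions(samples_per_tree)):
        for j in range(n):
            sample_ids.append(sample_id(tree, j + 1))
            meta_rows.append({"tree": tree, "position": j + 1})
            xs.append(axis[j])
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return samples_per_tree, np.asarray(xs), meta


def _library_sizes(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    s = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return s / np.exp(np.mean(np.log(s)))  # geometric mean 1


def simulate_series(config: SimulationConfig) -> tuple[SectionSeriesMatrix, SyntheticTruth]:
    """Simulate one cryosection-series count matrix with planted clusters.

    Each non-noise gene g in cluster c has expected profile
    ``base_g + amplitude_g * exp(-(x - peak_c)^2 / (2 w^2))`` along the axis
    coordinate x, scaled by the per-sample library size and sampled from a
    negative binomial.  Noise genes have a position-independent mean.

    Returns the count matrix (with per-sample tree/position metadata) and the
    planted :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    _, xs, meta = _sample_design(config, rng)
    n_samples = len(xs)

    peaks = (
        np.asarray(config.peak_positions)
        if config.peak_positions is not None
        else np.linspace(0.08, 0.92, config.n_clusters)
    )

    # gene -> cluster assignment: noise pool first (rounded), rest round-robin
    n_noise = int(round(config.noise_gene_fraction * config.n_genes))
    gene_ids = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    labels = np.empty(config.n_genes, dtype=object)
    perm = rng.permutation(config.n_genes)
    labels[perm[:n_noise]] = NOISE_LABEL
    for k, idx in enumerate(perm[n_noise:]):
        labels[idx] = _CLUSTER_LETTERS[k % config.n_clusters]

    # per-gene baseline and amplitude jitter (lognormal, mild)
    base = config.expression_base * rng.lognormal(0.0, 0.25, size=config.n_genes)
    gain = rng.lognormal(0.0, 0.25, size=config.n_genes)

    lib = _library_sizes(rng, n_samples, config.library_size_cv)

    mu = np.empty((config.n_genes, n_samples))
    for i, lab in enumerate(labels):
        if lab == NOISE_LABEL:
            mu[i] = base[i]
        else:
            peak = peaks[_CLUSTER_LETTERS.index(lab)]
            bump = np.exp(-((xs - peak) ** 2) / (2.0 * config.peak_width**2))
            mu[i] = base[i] + config.amplitude * gain[i] * bump
    mu *= lib[None, :]

    counts = _nb_draw(rng, mu, config.nb_dispersion)
    values = pd.DataFrame(counts, index=gene_ids, columns=meta.index)

    # TF labels and cluster-linked gene sets
    n_tf = int(round(config.tf_fraction * config.n_genes))
    tf_genes = set(np.asarray(gene_ids)[rng.permutation(config.n_genes)[:n_tf]])
    gene_sets: dict[str, set[str]] = {}
    for c in range(config.n_clusters):
        letter = _CLUSTER_LETTERS[c]
        members = [g for g, lab in zip(gene_ids, labels) if lab == letter]
        for t in range(config.n_terms):
            if not members:
                continue
            size = max(1, int(rng.integers(len(members) // 2 + 1, len(members) + 1)))
            chosen = rng.choice(members, size=min(size, len(members)), replace=False)
            gene_sets[f"SET_{letter}{t + 1}"] = set(chosen)

    cluster_label = dict(zip(gene_ids, labels))
    module_edges = [
        (gene_ids[i], gene_ids[j])
        for i in range(config.n_genes)
        for j in range(i + 1, config.n_genes)
        if labels[i] == labels[j] and labels[i] != NOISE_LABEL
    ]
    truth = SyntheticTruth(
        cluster_label=cluster_label,
        module_edges=module_edges,
        tf_genes=tf_genes,
        gene_sets=gene_sets,
    )

    matrix = SectionSeriesMatrix(values, meta, "counts")
    if config.missing_sample is not None:
        tree, pos = config.missing_sample
        sid = sample_id(tree, pos)
        if sid not in matrix.values.columns:
            raise ParameterError(f"missing_sample {sid} not in the simulated design")
        matrix = SectionSeriesMatrix(
            matrix.values.drop(columns=[sid]), matrix.sample_meta.drop(index=[sid]), "counts"
        )
    return matrix, truth


# ---------------------------------------------------------------------------


def _species_matrix(
    prefix: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    seed_latents: dict[int, float],
    seed_targets: dict[int, np.ndarray],
    seed_index: list[int],
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Counts for one pseudo-species given hub -> target wiring (by gene index)."""
    _, xs, meta = _sample_design(cfg, rng)
    n_samples = len(xs)
    base = cfg.expression_base * rng.lognormal(0.0, 0.25, size=cfg.n_genes)
    gain = rng.lognormal(0.0, 0.25, size=cfg.n_genes)
    lib = _library_sizes(rng, n_samples, cfg.library_size_cv)

    mu = np.tile(base[:, None], (1, n_samples)).astype(float)
    for s in seed_index:
        peak = seed_latents[s]
        bump = np.exp(-((xs - peak) ** 2) / (2.0 * cfg.peak_width**2))
        for g in np.concatenate(([s], seed_targets[s])):
            mu[g] = base[g] + cfg.amplitude * gain[g] * bump
    mu *= lib[None, :]
    counts = _nb_draw(rng, mu, cfg.nb_dispersion)
    gene_ids = [f"{prefix}{i:04d}" for i in range(1, cfg.n_genes + 1)]
    return pd.DataFrame(counts, index=gene_ids, columns=meta.index), meta


def simulate_species_pair(
    config: SimulationConfig,
    n_seeds: int,
    n_targets_per_seed: int,
    n_diverged: int,
    ortholog_missing_fraction: float = 0.0,
) -> tuple[SectionSeriesMatrix, SectionSeriesMatrix, SyntheticTruth]:
    """Two pseudo-species with planted hub modules and a 1:1 ortholog map.

    In species A each of ``n_seeds`` hub genes shares a Gaussian latent
    profile with its ``n_targets_per_seed`` targets (independent NB noise on
    top).  Species B repeats the construction on the orthologous genes except
    for ``n_diverged`` hubs, whose targets are replaced by an unrelated gene
    set; the orthologs of their original targets revert to flat noise.

    The ortholog map is 1:1 by gene index, with an optional fraction of pairs
    dropped to emulate missing orthology.
    """
    config.validate()
    if n_diverged > n_seeds:
        raise ParameterError("n_diverged must be <= n_seeds")
    needed = n_seeds * (2 * n_targets_per_seed + 1)
    if needed > config.n_genes:
        raise ParameterError(
            f"n_genes={config.n_genes} too small for {n_seeds} seeds with "
            f"{n_targets_per_seed} targets each plus rewiring pools ({needed} needed)"
        )
    if not 0.0 <= ortholog_missing_fraction < 1.0:
        raise ParameterError("ortholog_missing_fraction must be in [0, 1)")

    rng = np.random.default_rng(config.rng_seed)
    order = rng.permutation(config.n_genes)
    seeds = list(order[:n_seeds])
    cursor = n_seeds
    targets_a: dict[int, np.ndarray] = {}
    targets_b: dict[int, np.ndarray] = {}
    for s in seeds:
        targets_a[s] = order[cursor : cursor + n_targets_per_seed]
        cursor += n_targets_per_seed
    diverged = seeds[:n_diverged]
    for s in seeds:
        if s in diverged:
            targets_b[s] = order[cursor : cursor + n_targets_per_seed]  # unrelated pool
            cursor += n_targets_per_seed
        else:
            targets_b[s] = targets_a[s]
    latents = {s: p for s, p in zip(seeds, np.linspace(0.1, 0.9, n_seeds))}

    rng_a = np.random.default_rng(rng.integers(2**31))
    rng_b = np.random.default_rng(rng.integers(2**31))
    values_a, meta_a = _species_matrix("A", config, rng_a, latents, targets_a, seeds)
    values_b, meta_b = _species_matrix("B", config, rng_b, latents, targets_b, seeds)

    def aid(i: int) -> str:
        return f"A{i + 1:04d}"

    def bid(i: int) -> str:
        return f"B{i + 1:04d}"

    pairs = [(aid(i), bid(i)) for i in range(config.n_genes)]
    if ortholog_missing_fraction > 0:
        protected = set(seeds)
        for s in seeds:
            protected.update(targets_a[s])
            protected.update(targets_b[s])
        droppable = [k for k in range(config.n_genes) if k not in protected]
        n_drop = int(round(ortholog_missing_fraction * config.n_genes))
        drop = set(rng.choice(droppable, size=min(n_drop, len(droppable)), replace=False))
        pairs = [(a, b) for k, (a, b) in enumerate(pairs) if k not in drop]

    cluster_label = {aid(i): NOISE_LABEL for i in range(config.n_genes)}
    cluster_label.update({bid(i): NOISE_LABEL for i in range(config.n_genes)})
    module_edges = []
    for s in seeds:
        letter = _CLUSTER_LETTERS[seeds.index(s) % len(_CLUSTER_LETTERS)]
        for g in np.concatenate(([s], targets_a[s])):
            cluster_label[aid(int(g))] = letter
        for g in np.concatenate(([s], targets_b[s])):
            cluster_label[bid(int(g))] = letter
        module_edges += [(aid(int(s)), aid(int(g))) for g in targets_a[s]]
        module_edges += [(bid(int(s)), bid(int(g))) for g in targets_b[s]]

    truth = SyntheticTruth(
        cluster_label=cluster_label,
        module_edges=module_edges,
        tf_genes={aid(int(s)) for s in seeds} | {bid(int(s)) for s in seeds},
        seed_targets_a={aid(int(s)): {aid(int(g)) for g in targets_a[s]} for s in seeds},
        seed_targets_b={bid(int(s)): {bid(int(g)) for g in targets_b[s]} for s in seeds},
        diverged_seeds={aid(int(s)) for s in diverged},
        orthologs=pairs,
    )
    mat_a = SectionSeriesMatrix(values_a, meta_a, "counts")
    mat_b = SectionSeriesMatrix(values_b, meta_b, "counts")
    return mat_a, mat_b, truth
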