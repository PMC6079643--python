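"""Pipeline configuration: every stage parameter in one validated object.

Defaults mirror the constants of the analysis being reproduced: VST filter
threshold 3 (in >= 2 samples per tree, >= 2 trees), CLR network threshold 5
with 3.5 as the lower comparative preset, expansion threshold 5, 7 flat
clusters, variance cutoff 1, domain tolerance 4%, FDR alpha 0.05.

Configs load from a sectioned key = value text file (INI dialect); unknown
keys are rejected by name so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import configparser
from dataclasses import asdict, dataclass, fields

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocess
    vst_threshold: float = 3.0
    min_samples_per_tree: int = 2
    min_trees: int = 2
    dispersion_floor: float = 1e-6
    # network
    mi_bins: int | None = None  # None: floor(sqrt(n_samples))
    mi_scheme: str = "equal_frequency"
    clr_threshold: float = 5.0
    alt_threshold: float = 3.5
    expansion_threshold: float = 5.0
    scan_candidates: tuple[float, ...] | None = None  # None: fixed clr_threshold
    # clustering / domains
    min_sigma: float = 1.0
    sigma_statistic: str = "variance"
    n_clusters: int = 7
    domain_tolerance: float = 0.04
    enrichment_tree: str = "T1"
    # enrichment / comparative
    fdr_alpha: float = 0.05
    ortholog_mode: str = "any"
    # global
    rng_seed: int = 0

    def validate(self) -> None:
        if self.vst_threshold <= 0:
            raise ValueError("vst_threshold must be positive")
        if self.min_samples_per_tree < 1 or self.min_trees < 1:
            raise ValueError("min_samples_per_tree and min_trees must be >= 1")
        if self.mi_bins is not None and self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.mi_scheme not in ("equal_frequency", "equal_width", "bspline"):
            raise ValueError(f"unknown mi_scheme {self.mi_scheme!r}")
        if self.clr_threshold <= 0 or self.alt_threshold <= 0 or self.expansion_threshold <= 0:
            raise ValueError("CLR/expansion thresholds must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0.0 <= self.domain_tolerance < 1.0:
            raise ValueError("domain_tolerance must be in [0, 1)")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.sigma_statistic not in ("variance", "sd"):
            raise ValueError("sigma_statistic must be 'variance' or 'sd'")
        if self.ortholog_mode not in ("any", "best"):
            raise ValueError("ortholog_mode must be 'any' or 'best'")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load from a sectioned key=value file; section names are cosmetic.

        Unknown keys raise with the offending key named.  Keyword overrides
        (e.g. from CLI flags) take precedence over file values.
        """
        parser = configparser.ConfigParser()
        with open(path, encoding="utf-8") as fh:
            parser.read_file(fh)
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for section in parser.sections():
            for key, raw in parser.items(section):
                if key not in known:
                    raise ValueError(f"unknown configuration key {key!r} in section [{section}]")
                kwargs[key] = _coerce(key, raw)
        kwargs.update(overrides)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["scan_candidates"] is not None:
            d["scan_candidates"] = list(d["scan_candidates"])
        return d


_INT_KEYS = {"min_samples_per_tree", "min_trees", "mi_bins", "n_clusters", "rng_seed"}
_FLOAT_KEYS = {
    "vst_threshold", "dispersion_floor", "clr_threshold", "alt_threshold",
    "expansion_threshold", "min_sigma", "domain_tolerance", "fdr_alpha",
}


def _coerce(key: str, raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    if key == "scan_candidates":
        return tuple(float(v) for v in raw.replace(",", " ").split())
    if key in _INT_KEYS:
        return int(raw)
    if key in _FLOAT_KEYS:
        return float(raw)
    return raw
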