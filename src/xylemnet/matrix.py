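"""Gene x sample expression matrix for a cryosection series.

The central container of the pipeline: a gene-by-sample value table whose
columns are tangential cryosections pooled along the wood-developmental axis
(cambium -> expanding xylem -> secondary cell wall -> programmed cell death
-> mature xylem), collected from several replicate trees.  Sample identifiers
encode replicate tree and section position as ``T1:03``; positions within a
tree are strictly increasing in the order of sampling from the phloem side
inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SectionSeriesMatrix", "sample_id"]


def sample_id(tree: str, position: int) -> str:
    """Canonical sample identifier, e.g. ``sample_id("T1", 3) == "T1:03"``."""
    return f"{tree}:{int(position):02d}"


@dataclass
class SectionSeriesMatrix:
    """Expression values for genes across a section series.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes (rows) by samples (columns).  For ``value_kind="counts"`` all
        entries must be finite non-negative integers; for ``"vst"`` any
        finite reals.
    sample_meta : pandas.DataFrame
        Indexed by sample ID, with columns ``tree`` (str) and ``position``
        (int >= 1).  Within each tree, positions must be strictly increasing
        in column order.
    value_kind : {"counts", "vst"}
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "vst"):
            raise ValueError(f"value_kind must be 'counts' or 'vst', got {self.value_kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.values.columns]
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite entries")
        if self.value_kind == "counts":
            if (arr < 0).any():
                raise ValueError("count matrix contains negative entries")
        # positions strictly increasing within each tree, in column order
        for tree, meta in self.sample_meta.groupby("tree", sort=False):
            pos = meta["position"].to_numpy()
            if (pos < 1).any():
                raise ValueError(f"tree {tree}: positions must be >= 1")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"tree {tree}: positions not strictly increasing in column order")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def trees(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.sample_meta["tree"]:
            seen.setdefault(t, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of_tree(self, tree: str) -> list[str]:
        if tree not in set(self.sample_meta["tree"]):
            raise KeyError(f"unknown tree {tree!r}")
        return list(self.sample_meta.index[self.sample_meta["tree"] == tree])

    def subset_genes(self, genes) -> "SectionSeriesMatrix":
        genes = list(genes)
        unknown = set(genes) - set(self.values.index)
        if unknown:
            raise KeyError(f"genes not in matrix: {sorted(unknown)}")
        return SectionSeriesMatrix(self.values.loc[genes], self.sample_meta.copy(), self.value_kind)

    def copy(self) -> "SectionSeriesMatrix":
        return SectionSeriesMatrix(self.values.copy(), self.sample_meta.copy(), self.value_kind)
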