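"""Shared in-memory containers for depth-stratified community data.

The central object is :class:`CommunityMatrix`: a taxon x sample table of
sequence counts together with per-sample metadata (depth layer index and
season label). Every downstream stage — community statistics, null models,
niche breadth, the random-forest screen — consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CommunityMatrix"]


@dataclass
class CommunityMatrix:
    """Taxon x sample count matrix with per-sample layer/season labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; rows are taxa, columns are samples.
    sample_meta : pandas.DataFrame
        Indexed by sample id; must contain a ``layer`` column (integer depth
        layer, 1 = surface) and a ``season`` column (arbitrary label).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            # one pseudo-layer per sample, single season
            self.sample_meta = pd.DataFrame(
                {"layer": np.arange(1, self.counts.shape[1] + 1), "season": "all"},
                index=self.counts.columns,
            )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate taxon ids in counts")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in counts")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        for col in ("layer", "season"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")

    # ------------------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def layers(self) -> list[int]:
        """Sorted distinct layer indices present in the metadata."""
        return sorted(int(x) for x in self.sample_meta.loc[self.sample_ids, "layer"].unique())

    def samples_in_layer(self, layer: int) -> list[str]:
        meta = self.sample_meta.loc[self.sample_ids]
        return list(meta.index[meta["layer"] == layer])

    def subset_samples(self, samples: list[str]) -> "CommunityMatrix":
        return CommunityMatrix(
            self.counts[list(samples)].copy(), self.sample_meta.loc[list(samples)].copy()
        )

    def relative_abundance(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=0)
        if (sums == 0).any():
            bad = list(sums.index[sums == 0])
            raise ValueError(f"samples with zero total counts: {bad}")
        return self.counts / sums

    # ------------------------------------------------------------------
    def to_tsv(self, counts_path, meta_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="taxon_id")
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, meta_path=None) -> "CommunityMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)
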