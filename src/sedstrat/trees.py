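"""Phylogenetic tree helpers: patristic distances and clade groupings.

Trees are dendropy objects throughout; taxa are matched to community
matrices by tip label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = ["read_tree", "write_tree", "patristic_matrix", "clade_groups", "check_tips_cover"]


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip patristic (branch-length) distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def check_tips_cover(tree: dendropy.Tree, taxon_ids) -> None:
    """Raise if any community taxon is absent from the tree tips."""
    tips = {t.label for t in tree.taxon_namespace}
    missing = sorted(set(taxon_ids) - tips)
    if missing:
        raise ValueError(f"taxa absent from tree tips: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))


def clade_groups(dist: pd.DataFrame, n_groups: int, prefix: str = "Clade") -> pd.Series:
    """Partition taxa into ``n_groups`` clade-like groups by average-linkage
    clustering of patristic distances; used to emulate coarse taxonomic
    ranks (phylum/class) on simulated trees."""
    z = average(squareform(dist.to_numpy(), checks=False))
    labels = fcluster(z, t=n_groups, criterion="maxclust")
    width = len(str(int(labels.max())))
    names = [f"{prefix}_{k:0{width}d}" for k in labels]
    return pd.Series(names, index=dist.index, name="group")
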