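"""Random-forest screening of damming-sensitive taxa.

Samples are labelled pre- vs post-damming by the depth horizon; taxa
(relative abundances, usually aggregated to phylum or class rank) are the
features. An ensemble of independently seeded random forests is pooled by
averaging mean-decrease-Gini importances, classification quality is
reported as the mean out-of-bag (OOB) error, and the descending importance
curve is segmented by least-squares breakpoints — the taxa ranked before
the first breakpoint are the "damming-sensitive" set. An unsupervised
random-forest clustering (real vs synthetic contrast, proximity-based)
cross-checks the two-zone structure without using the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ImportanceRanking",
    "rf_importance_ensemble",
    "piecewise_constant_breaks",
    "importance_breakpoints",
    "RFClusteringResult",
    "unsupervised_rf_clustering",
]


# ----------------------------------------------------------------------
@dataclass
class ImportanceRanking:
    """Pooled Gini importances, descending, with optional breakpoint selection."""

    table: pd.DataFrame            # columns: taxon, importance, rank, selected
    oob_error: float
    n_forests: int
    breakpoints: list[int] = field(default_factory=list)  # positions in rank order

    @property
    def selected_taxa(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "taxon"])


def rf_importance_ensemble(
    features: pd.DataFrame,
    labels,
    n_forests: int = 100,
    n_trees: int = 1000,
    seed=None,
    balanced: bool = True,
) -> ImportanceRanking:
    """Ensemble of random forests pooled into one importance ranking.

    ``features`` is samples x taxa (relative abundances); ``labels`` a
    two-class vector (e.g. "pre"/"post"). Each of the ``n_forests``
    replicates trains an independently seeded forest of ``n_trees`` trees;
    pooled importance is the arithmetic mean of per-forest mean-decrease-
    Gini values and the OOB error is the mean replicate OOB
    misclassification rate. ``balanced=True`` reweights classes per
    bootstrap to damp pre/post sample-count imbalance.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if len(y) != features.shape[0]:
        raise ValueError("labels length does not match feature rows")
    x = features.to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    imps = np.zeros(features.shape[1])
    oob = 0.0
    for child in ss.spawn(n_forests):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features="sqrt",
            oob_score=True,
            class_weight="balanced_subsample" if balanced else None,
            random_state=np.random.default_rng(child).integers(2 ** 31),
            n_jobs=1,
        )
        rf.fit(x, y)
        imps += rf.feature_importances_
        oob += 1.0 - rf.oob_score_
    imps /= n_forests
    oob /= n_forests
    order = np.argsort(-imps, kind="stable")
    table = pd.DataFrame(
        {
            "taxon": features.columns[order],
            "importance": imps[order],
            "rank": np.arange(1, len(order) + 1),
            "selected": False,
        }
    )
    return ImportanceRanking(table=table, oob_error=float(oob), n_forests=n_forests)


# ----------------------------------------------------------------------
def _segment_cost(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """RSS of the constant fit on y[i:j] (half-open)."""
    n = j - i
    s = prefix[j] - prefix[i]
    sq = prefix_sq[j] - prefix_sq[i]
    return sq - s * s / n


def piecewise_constant_breaks(
    y, max_breaks: int, min_size: int = 2
) -> tuple[list[int], float]:
    """Optimal piecewise-constant segmentation of a sequence.

    Dynamic programming over all segmentations with up to ``max_breaks``
    breakpoints (segments at least ``min_size`` long); the number of breaks
    is chosen by BIC. Returns (break positions as indices where a new
    segment starts, RSS of the chosen segmentation).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_size:
        raise ValueError("series too short to segment")
    if max_breaks >= n / 2:
        raise ValueError("max_breaks must be smaller than n/2")
    prefix = np.concatenate([[0.0], np.cumsum(y)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(y ** 2)])

    # cost[k][j] = min RSS of fitting y[:j] with exactly k breaks
    inf = np.inf
    cost = np.full((max_breaks + 1, n + 1), inf)
    back = np.zeros((max_breaks + 1, n + 1), dtype=int)
    for j in range(min_size, n + 1):
        cost[0][j] = _segment_cost(prefix, prefix_sq, 0, j)
    for k in range(1, max_breaks + 1):
        for j in range((k + 1) * min_size, n + 1):
            best, arg = inf, 0
            for t in range(k * min_size, j - min_size + 1):
                c = cost[k - 1][t] + _segment_cost(prefix, prefix_sq, t, j)
                if c < best:
                    best, arg = c, t
            cost[k][j], back[k][j] = best, arg

    # BIC model selection over k
    eps = 1e-12
    best_k, best_bic = 0, inf
    for k in range(max_breaks + 1):
        rss = cost[k][n]
        if not np.isfinite(rss):
            continue
        p = 2 * k + 1  # k breakpoints + (k+1) segment means - shared scale
        bic = n * np.log(max(rss, eps) / n) + p * np.log(n)
        if bic < best_bic - 1e-9:
            best_k, best_bic = k, bic
    breaks = []
    j = n
    for k in range(best_k, 0, -1):
        t = back[k][j]
        breaks.append(t)
        j = t
    breaks.reverse()
    return breaks, float(cost[best_k][n])


def importance_breakpoints(ranking: ImportanceRanking, max_breaks: int = 3) -> ImportanceRanking:
    """Segment the descending importance curve and mark the selected prefix.

    The taxa ranked before the first breakpoint form the damming-sensitive
    set; with no breakpoint found, nothing is selected.
    """
    y = ranking.table["importance"].to_numpy()
    if len(y) < 4:
        raise ValueError("need at least 4 ranked values")
    breaks, _ = piecewise_constant_breaks(y, max_breaks=max_breaks)
    table = ranking.table.copy()
    table["selected"] = False
    if breaks:
        table.iloc[: breaks[0], table.columns.get_loc("selected")] = True
    return ImportanceRanking(
        table=table, oob_error=ranking.oob_error, n_forests=ranking.n_forests,
        breakpoints=breaks,
    )


# ----------------------------------------------------------------------
@dataclass
class RFClusteringResult:
    proximity: pd.DataFrame
    coordinates: pd.DataFrame    # 2-D classical scaling of 1 - proximity
    clusters: pd.Series          # k=2 average-linkage partition


def unsupervised_rf_clustering(
    features: pd.DataFrame, n_trees: int = 1000, seed=None
) -> RFClusteringResult:
    """Unsupervised random-forest clustering of samples.

    A synthetic contrast class is drawn from the product of the feature
    marginals (each column permuted independently); a forest learns real vs
    synthetic, and the proximity of two real samples is the fraction of
    trees in which they share a leaf. Classical scaling of 1 - proximity
    gives 2-D coordinates; an average-linkage k=2 cut gives the partition.
    """
    if features.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    x = features.to_numpy(dtype=float)
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("degenerate constant features")
    rng = np.random.default_rng(seed)
    synth = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
    xx = np.vstack([x, synth])
    yy = np.concatenate([np.zeros(len(x)), np.ones(len(synth))])
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt",
        random_state=int(rng.integers(2 ** 31)), n_jobs=1,
    )
    rf.fit(xx, yy)
    leaves = rf.apply(x)  # real samples only: n_samples x n_trees
    n = len(x)
    prox = np.zeros((n, n))
    for i in range(n):
        prox[i] = (leaves == leaves[i]).mean(axis=1)
    prox = (prox + prox.T) / 2
    np.fill_diagonal(prox, 1.0)
    dist = 1.0 - prox
    # classical scaling (local import avoids a cycle at module load)
    from .community import pcoa

    dd = pd.DataFrame(dist, index=features.index, columns=features.index)
    coords = pcoa(dd, k=2).coordinates
    z = linkage(squareform(dist, checks=False), method="average")
    clusters = pd.Series(fcluster(z, t=2, criterion="maxclust"), index=features.index,
                         name="cluster")
    return RFClusteringResult(
        proximity=pd.DataFrame(prox, index=features.index, columns=features.index),
        coordinates=coords,
        clusters=clusters,
    )
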