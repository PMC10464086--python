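"""Depth-resolved community structure statistics.

Rarefaction, alpha diversity (Chao1, Pielou), Bray-Curtis / binary-Jaccard
dissimilarities, principal coordinates analysis, UPGMA clustering, ANOSIM,
the abundance-based multiple-site dissimilarity partition (balanced
variation vs abundance gradients), seasonal pooling, and the
bipartite-network connection degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio.diversity.alpha import chao1, pielou_e

from .containers import CommunityMatrix

__all__ = [
    "rarefy",
    "alpha_diversity",
    "dissimilarity",
    "pcoa",
    "PCoAResult",
    "upgma",
    "UPGMAResult",
    "anosim",
    "multi_timepoint_dissimilarity",
    "merge_seasons",
    "connection_degree",
]


# ----------------------------------------------------------------------
def rarefy(m: CommunityMatrix, depth="min", seed: int | None = None) -> CommunityMatrix:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    ``depth="min"`` uses the smallest sample total. Deterministic under
    ``seed`` (one multivariate-hypergeometric draw per sample).
    """
    sums = m.sample_sums()
    if depth == "min":
        depth = int(sums.min())
    depth = int(depth)
    too_small = sums.index[sums < depth]
    if len(too_small):
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: {list(too_small)}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    counts = m.counts
    for s in counts.columns:
        col = counts[s].to_numpy()
        if not np.issubdtype(col.dtype, np.integer):
            if not np.allclose(col, np.round(col)):
                raise ValueError(f"non-integer counts in sample {s}")
            col = np.round(col).astype(np.int64)
        out[s] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return CommunityMatrix(rare, m.sample_meta.loc[counts.columns].copy())


# ----------------------------------------------------------------------
def alpha_diversity(m: CommunityMatrix) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Pielou's evenness, observed richness.

    Chao1 uses the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)), so
    it is defined when no doubletons occur. Pielou is Shannon (natural log)
    over ln(S_obs), reported as NaN when S_obs <= 1.
    """
    rows = {}
    arr = m.counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer counts")
    for s in m.sample_ids:
        col = np.round(m.counts[s].to_numpy()).astype(np.int64)
        obs = int((col > 0).sum())
        c1 = chao1(col, bias_corrected=True) if obs > 0 else np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pe = pielou_e(col) if obs > 1 else np.nan
        rows[s] = {"chao1": c1, "pielou": pe, "observed_richness": obs}
    return pd.DataFrame(rows).T.loc[m.sample_ids]


# ----------------------------------------------------------------------
def dissimilarity(
    m: CommunityMatrix, metric: str = "bray_curtis", relative: bool = False
) -> pd.DataFrame:
    """Pairwise sample dissimilarity matrix.

    ``bray_curtis`` on counts (or per-sample relative abundances when
    ``relative=True``); ``jaccard_binary`` on presence/absence.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sums = m.sample_sums()
    if (sums == 0).any():
        raise ValueError(f"samples with zero totals: {list(sums.index[sums == 0])}")
    x = m.counts.to_numpy(dtype=float).T  # samples x taxa
    if metric == "bray_curtis":
        if relative:
            x = x / x.sum(axis=1, keepdims=True)
        d = pdist(x, metric="braycurtis")
    elif metric == "jaccard_binary":
        d = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=m.sample_ids, columns=m.sample_ids)


def _check_square(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    return a


# ----------------------------------------------------------------------
@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_mass: float           # sum of |negative eigenvalues|


def pcoa(d: pd.DataFrame, k: int = 2) -> PCoAResult:
    """Classical principal coordinates analysis (Gower double-centering).

    Negative eigenvalues are reported, not corrected; proportions explained
    are computed over positive eigenvalues, with the absolute negative mass
    returned alongside.
    """
    a = _check_square(d)
    n = a.shape[0]
    if not k < n:
        raise ValueError("k must be smaller than the number of samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (a ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[:k], 0, None)
    coords = evecs[:, :k] * np.sqrt(pos)
    prop = np.clip(evals, 0, None)
    prop = prop / prop.sum() if prop.sum() > 0 else prop
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=d.index, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals,
        proportion_explained=prop[:k],
        negative_mass=float(-evals[evals < 0].sum()),
    )


# ----------------------------------------------------------------------
@dataclass
class UPGMAResult:
    linkage: np.ndarray           # scipy linkage matrix (cophenetic distances)
    labels: list[str]             # sample order used (lexicographic)

    @property
    def merge_heights(self) -> np.ndarray:
        """Ultrametric node heights (half the cophenetic merge distance)."""
        return self.linkage[:, 2] / 2.0

    def cut(self, k: int) -> pd.Series:
        flat = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def upgma(d: pd.DataFrame) -> UPGMAResult:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    Samples are ordered lexicographically before linkage so tie-breaking is
    deterministic.
    """
    _check_square(d)
    labels = sorted(map(str, d.index))
    a = d.loc[labels, labels].to_numpy(dtype=float)
    z = linkage(squareform(a, checks=False), method="average")
    return UPGMAResult(linkage=z, labels=labels)


# ----------------------------------------------------------------------
def anosim(
    d: pd.DataFrame, groups, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranked pairs; the p-value uses label permutations with the
    add-one rule, p = (#{R_perm >= R_obs} + 1) / (n_perm + 1).
    """
    a = _check_square(d)
    groups = pd.Series(groups, index=d.index) if not isinstance(groups, pd.Series) else groups
    g = groups.loc[d.index].to_numpy()
    labels, sizes = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValueError(f"singleton groups: {list(labels[sizes < 2])}")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = rankdata(a[iu])
    m_pairs = len(ranks)

    def r_stat(gvec: np.ndarray) -> float:
        within = gvec[iu[0]] == gvec[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m_pairs / 2.0)

    r_obs = r_stat(g)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(g)) >= r_obs:
            count += 1
    return float(r_obs), (count + 1) / (n_perm + 1)


# ----------------------------------------------------------------------
def multi_timepoint_dissimilarity(m: CommunityMatrix) -> dict[str, float]:
    """Abundance-based multiple-site Bray-Curtis dissimilarity partition.

    For the seasonal snapshots of one layer this measures temporal
    community fluctuation, split (after Baselga) into a balanced-variation
    component and an abundance-gradient component:

        total    = (S_min + S_max) / (2*S_A + S_min + S_max)
        balanced = S_min / (S_A + S_min)
        gradient = total - balanced

    with, over site pairs i<j, b_ij = sum_s max(0, x_si - x_sj),
    S_min = sum min(b_ij, b_ji), S_max = sum max(b_ij, b_ji) and
    S_A = sum_s sum min(x_si, x_sj).
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples (timepoints)")
    x = m.counts.to_numpy(dtype=float).T  # sites x taxa
    n = x.shape[0]
    s_min = s_max = s_a = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            diff = x[i] - x[j]
            b_ij = np.clip(diff, 0, None).sum()
            b_ji = np.clip(-diff, 0, None).sum()
            s_min += min(b_ij, b_ji)
            s_max += max(b_ij, b_ji)
            s_a += np.minimum(x[i], x[j]).sum()
    denom = 2 * s_a + s_min + s_max
    total = (s_min + s_max) / denom if denom > 0 else 0.0
    balanced = s_min / (s_a + s_min) if (s_a + s_min) > 0 else 0.0
    return {"total": total, "balanced": balanced, "gradient": total - balanced}


# ----------------------------------------------------------------------
def merge_seasons(m: CommunityMatrix) -> CommunityMatrix:
    """Pool counts of all seasonal samples of the same layer (one sample
    per layer in the output, labelled ``L<layer>``)."""
    meta = m.sample_meta.loc[m.sample_ids]
    merged = {}
    layers = m.layers()
    for layer in layers:
        cols = m.samples_in_layer(layer)
        merged[f"L{layer:02d}"] = m.counts[cols].sum(axis=1)
    counts = pd.DataFrame(merged, index=m.counts.index)
    new_meta = pd.DataFrame(
        {"layer": layers, "season": "merged"}, index=list(counts.columns)
    )
    return CommunityMatrix(counts, new_meta)


# ----------------------------------------------------------------------
def connection_degree(m: CommunityMatrix, threshold: float = 10.0) -> pd.Series:
    """Per-taxon count of samples it is connected to in the OTU-sample
    bipartite network: an edge exists iff log10(abundance) >= 1, i.e.
    abundance >= 10 reads (threshold inclusive)."""
    deg = (m.counts.to_numpy() >= threshold).sum(axis=1)
    return pd.Series(deg, index=m.taxon_ids, name="degree")
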