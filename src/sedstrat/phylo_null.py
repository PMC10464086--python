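"""Phylogenetic null-model inference of community assembly processes.

Implements the standard null-model stack used to partition assembly into
ecological processes:

* MNTD / betaMNTD — (between-)community mean nearest-taxon patristic
  distance, optionally abundance-weighted;
* NTI / betaNTI — standardized effect sizes of MNTD / betaMNTD against a
  null that shuffles taxa across the tips of the phylogeny (999
  randomizations by default); |betaNTI| > 2 indicates selection
  (heterogeneous if > +2, homogeneous if < -2);
* RC_bray — the Bray-Curtis-based Raup-Crick metric in [-1, 1], comparing
  observed Bray-Curtis to nulls that preserve each community's richness and
  total abundance while drawing taxa from the metacommunity (9999
  randomizations by default);
* the five-way partition: heterogeneous selection, homogeneous selection,
  dispersal limitation (|betaNTI| < 2, RC > 0.95), homogenizing dispersal
  (|betaNTI| < 2, RC < -0.95) and drift (the remainder);
* adjacent-layer betaNTI/RC profiles down a sediment column, on seasonal
  snapshots or seasonally pooled samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import merge_seasons
from .containers import CommunityMatrix
from .trees import check_tips_cover, patristic_matrix

__all__ = [
    "mntd",
    "beta_mntd",
    "nti",
    "bnti",
    "raup_crick_bray",
    "partition_processes",
    "AssemblyResult",
    "assembly_analysis",
    "adjacent_layer_profile",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ----------------------------------------------------------------------
def _as_vector(abund, dist: pd.DataFrame) -> np.ndarray:
    """Align an abundance vector (Series or array) to the distance matrix."""
    if isinstance(abund, pd.Series):
        v = abund.reindex(dist.index, fill_value=0.0).to_numpy(dtype=float)
    else:
        v = np.asarray(abund, dtype=float)
        if v.shape[0] != dist.shape[0]:
            raise ValueError("abundance vector length does not match distance matrix")
    if (v < 0).any():
        raise ValueError("negative abundances")
    return v


def _mntd_idx(present: np.ndarray, weights: np.ndarray, d: np.ndarray) -> float:
    sub = d[np.ix_(present, present)]
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    return float(nearest @ weights)


def mntd(abund, dist: pd.DataFrame, weighted: bool = True) -> float:
    """Mean nearest-taxon distance of one community.

    For each present taxon the distance to its nearest present relative is
    taken; ``weighted=True`` averages with relative abundances, otherwise
    arithmetically.
    """
    v = _as_vector(abund, dist)
    present = np.flatnonzero(v > 0)
    if present.size < 2:
        raise ValueError("MNTD needs at least 2 present taxa")
    w = v[present] / v[present].sum() if weighted else np.full(present.size, 1.0 / present.size)
    return _mntd_idx(present, w, dist.to_numpy())


def _beta_mntd_idx(
    i1: np.ndarray, w1: np.ndarray, i2: np.ndarray, w2: np.ndarray, d: np.ndarray
) -> float:
    d12 = d[np.ix_(i1, i2)]
    return 0.5 * float(d12.min(axis=1) @ w1 + d12.min(axis=0) @ w2)


def beta_mntd(c1, c2, dist: pd.DataFrame, weighted: bool = True) -> float:
    """Between-community analogue of MNTD (betaMNTD).

    0.5 * [sum_s f_s1 * min_{t in c2} d(s,t) + sum_s f_s2 * min_{t in c1} d(s,t)];
    a taxon shared by both communities contributes distance 0.
    """
    v1, v2 = _as_vector(c1, dist), _as_vector(c2, dist)
    i1, i2 = np.flatnonzero(v1 > 0), np.flatnonzero(v2 > 0)
    if i1.size == 0 or i2.size == 0:
        raise ValueError("betaMNTD needs two non-empty communities")
    w1 = v1[i1] / v1[i1].sum() if weighted else np.full(i1.size, 1.0 / i1.size)
    w2 = v2[i2] / v2[i2].sum() if weighted else np.full(i2.size, 1.0 / i2.size)
    return _beta_mntd_idx(i1, w1, i2, w2, dist.to_numpy())


# ----------------------------------------------------------------------
def _ses(obs: float, nulls: np.ndarray, negate: bool) -> float:
    mu, sd = nulls.mean(), nulls.std(ddof=1)
    if sd == 0:
        warnings.warn("null distribution has zero spread; index undefined", UserWarning,
                      stacklevel=3)
        return float("nan")
    z = (obs - mu) / sd
    return -z if negate else z


def nti(abund, dist: pd.DataFrame, n_null: int = 999, seed=None, weighted: bool = True) -> float:
    """Nearest taxon index: -(MNTD_obs - mean MNTD_null) / sd MNTD_null.

    Nulls shuffle taxa across all tips of the distance matrix. Positive NTI
    means the community is phylogenetically clustered. Returns NaN (with a
    warning) when the null spread is zero, e.g. on a star-like tree.
    """
    v = _as_vector(abund, dist)
    present = np.flatnonzero(v > 0)
    if present.size < 2:
        raise ValueError("NTI needs at least 2 present taxa")
    w = v[present] / v[present].sum() if weighted else np.full(present.size, 1.0 / present.size)
    d = dist.to_numpy()
    obs = _mntd_idx(present, w, d)
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    nulls = np.empty(n_null)
    for k in range(n_null):
        perm = rng.permutation(n)
        nulls[k] = _mntd_idx(perm[present], w, d)
    return _ses(obs, nulls, negate=True)


def bnti(
    c1, c2, dist: pd.DataFrame, n_null: int = 999, seed=None,
    weighted: bool = True, pool: str = "all",
) -> float:
    """betaNTI: (betaMNTD_obs - mean betaMNTD_null) / sd betaMNTD_null.

    Each null replicate draws one permutation of tip labels and applies it
    to both communities of the pair, preserving their shared-taxon
    structure; abundances stay fixed. ``pool="all"`` shuffles across every
    tip of the distance matrix (metacommunity-wide null); ``pool="pair"``
    restricts shuffling to the taxa present in either community.
    """
    v1, v2 = _as_vector(c1, dist), _as_vector(c2, dist)
    i1, i2 = np.flatnonzero(v1 > 0), np.flatnonzero(v2 > 0)
    if i1.size == 0 or i2.size == 0:
        raise ValueError("betaNTI needs two non-empty communities")
    w1 = v1[i1] / v1[i1].sum() if weighted else np.full(i1.size, 1.0 / i1.size)
    w2 = v2[i2] / v2[i2].sum() if weighted else np.full(i2.size, 1.0 / i2.size)
    d = dist.to_numpy()
    obs = _beta_mntd_idx(i1, w1, i2, w2, d)
    n = d.shape[0]
    if pool == "all":
        universe = np.arange(n)
    elif pool == "pair":
        universe = np.union1d(i1, i2)
    else:
        raise ValueError("pool must be 'all' or 'pair'")
    # map community indices to positions within the shuffled universe
    pos = np.full(n, -1)
    pos[universe] = np.arange(universe.size)
    p1, p2 = pos[i1], pos[i2]
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    for k in range(n_null):
        perm = universe[rng.permutation(universe.size)]
        nulls[k] = _beta_mntd_idx(perm[p1], w1, perm[p2], w2, d)
    return _ses(obs, nulls, negate=False)


# ----------------------------------------------------------------------
def rc_score(n_below: int, n_ties: int, n_null: int) -> float:
    """Raup-Crick scaling to [-1, 1]: 2*[(below + ties/2)/n_null] - 1."""
    return 2.0 * ((n_below + 0.5 * n_ties) / n_null) - 1.0


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    s = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / s) if s > 0 else 0.0


def _null_community(
    rng: np.random.Generator, richness: int, total: int,
    occ_p: np.ndarray, abund_p: np.ndarray,
) -> np.ndarray:
    """One Raup-Crick null community: draw ``richness`` distinct taxa with
    probability proportional to metacommunity occurrence frequency, then
    distribute the remaining individuals in proportion to metacommunity
    relative abundance of the drawn taxa."""
    n = occ_p.size
    chosen = rng.choice(n, size=richness, replace=False, p=occ_p)
    out = np.zeros(n)
    out[chosen] = 1.0
    rest = total - richness
    if rest > 0:
        p = abund_p[chosen]
        psum = p.sum()
        p = p / psum if psum > 0 else np.full(richness, 1.0 / richness)
        out[chosen] += rng.multinomial(rest, p)
    return out


def raup_crick_bray(
    c1, c2, metacommunity: CommunityMatrix, n_null: int = 9999, seed=None
) -> float:
    """Bray-Curtis-based Raup-Crick metric RC_bray in [-1, 1].

    Null pairs preserve each community's observed richness and total count;
    taxon identities are drawn without replacement with probability
    proportional to occurrence frequency across the metacommunity, and the
    remaining individuals are assigned in proportion to metacommunity total
    relative abundance. Bray-Curtis is computed on relative abundances;
    ties between BC_null and BC_obs count half:

        RC = 2 * [(#{BC_null < BC_obs} + 0.5 * #{BC_null = BC_obs}) / n_null] - 1
    """
    counts = metacommunity.counts
    taxa = counts.index
    if isinstance(c1, pd.Series):
        c1 = c1.reindex(taxa, fill_value=0.0)
    if isinstance(c2, pd.Series):
        c2 = c2.reindex(taxa, fill_value=0.0)
    x = np.asarray(c1, dtype=float)
    y = np.asarray(c2, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("RC_bray needs two non-empty communities")
    occ = (counts.to_numpy() > 0).sum(axis=1).astype(float)
    tot = counts.sum(axis=1).to_numpy(dtype=float)
    occ_p = occ / occ.sum()
    abund_p = tot / tot.sum()
    obs = _bray(x / x.sum(), y / y.sum())
    r1, n1 = int((x > 0).sum()), int(round(x.sum()))
    r2, n2 = int((y > 0).sum()), int(round(y.sum()))
    rng = np.random.default_rng(seed)
    below = ties = 0
    for _ in range(n_null):
        a = _null_community(rng, r1, n1, occ_p, abund_p)
        b = _null_community(rng, r2, n2, occ_p, abund_p)
        bc = _bray(a / a.sum(), b / b.sum())
        if bc < obs - 1e-12:
            below += 1
        elif bc <= obs + 1e-12:
            ties += 1
    return rc_score(below, ties, n_null)


# ----------------------------------------------------------------------
def classify_pair(bnti_value: float, rc_value: float | None) -> str:
    """Five-way process label for one pairwise comparison."""
    if np.isnan(bnti_value):
        return "undefined"
    if bnti_value > 2:
        return "heterogeneous_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value is None or np.isnan(rc_value):
        return "undefined"
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(bnti_values, rc_values) -> tuple[dict[str, float], list[str]]:
    """Fractions of pairwise comparisons assigned to each assembly process.

    ``bnti_values`` and ``rc_values`` must be aligned over the same pair
    set. Returns (fractions summing to 1, per-pair labels).
    """
    b = np.asarray(bnti_values, dtype=float)
    r = np.asarray(rc_values, dtype=float)
    if b.shape != r.shape:
        raise ValueError("betaNTI and RC value sets have mismatched pair sets")
    labels = [classify_pair(bv, rv) for bv, rv in zip(b, r)]
    valid = [lab for lab in labels if lab != "undefined"]
    n = len(valid)
    if n == 0:
        raise ValueError("no classifiable pairs")
    fractions = {p: valid.count(p) / n for p in PROCESSES}
    return fractions, labels


# ----------------------------------------------------------------------
@dataclass
class AssemblyResult:
    """Pairwise betaNTI / RC_bray values and the derived process fractions."""

    pairs: list[tuple[str, str]]
    bnti: np.ndarray
    rc: np.ndarray
    labels: list[str] = field(default_factory=list)
    fractions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_1": [p[0] for p in self.pairs],
                "sample_2": [p[1] for p in self.pairs],
                "bnti": self.bnti,
                "rc_bray": self.rc,
                "process": self.labels,
            }
        )


def assembly_analysis(
    m: CommunityMatrix, tree, pairs=None, n_null: int = 999,
    n_null_rc: int = 9999, seed=None, weighted: bool = True,
) -> AssemblyResult:
    """betaNTI + RC_bray over sample pairs, with the five-way partition.

    ``pairs`` defaults to all unordered sample pairs. The metacommunity for
    the Raup-Crick null is the full matrix ``m``.
    """
    check_tips_cover(tree, m.taxon_ids)
    dist = patristic_matrix(tree).loc[m.taxon_ids, m.taxon_ids]
    if pairs is None:
        ids = m.sample_ids
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(2 * len(pairs))
    bnti_vals = np.empty(len(pairs))
    rc_vals = np.empty(len(pairs))
    for k, (s1, s2) in enumerate(pairs):
        c1, c2 = m.counts[s1], m.counts[s2]
        bnti_vals[k] = bnti(c1, c2, dist, n_null=n_null, seed=children[2 * k],
                            weighted=weighted)
        rc_vals[k] = raup_crick_bray(c1, c2, m, n_null=n_null_rc, seed=children[2 * k + 1])
    fractions, labels = partition_processes(bnti_vals, rc_vals)
    return AssemblyResult(pairs=list(pairs), bnti=bnti_vals, rc=rc_vals,
                          labels=labels, fractions=fractions)


# ----------------------------------------------------------------------
def adjacent_layer_profile(
    m: CommunityMatrix, tree, mode: str = "merged", n_null: int = 999,
    n_null_rc: int = 999, seed=None, weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI and RC_bray for every adjacent-layer boundary down the column.

    ``mode="merged"`` pools seasons first (one comparison per boundary);
    ``mode="snapshots"`` compares same-season samples of adjacent layers
    (one comparison per boundary per season). Boundaries whose layers have
    no samples are skipped with a warning. Output rows are ordered by
    boundary depth.
    """
    if mode == "merged":
        mm = merge_seasons(m)
        frames = [("merged", mm)]
    elif mode == "snapshots":
        frames = []
        for season in pd.unique(m.sample_meta.loc[m.sample_ids, "season"]):
            cols = [s for s in m.sample_ids if m.sample_meta.loc[s, "season"] == season]
            frames.append((season, m.subset_samples(cols)))
    else:
        raise ValueError("mode must be 'merged' or 'snapshots'")

    check_tips_cover(tree, m.taxon_ids)
    dist = patristic_matrix(tree).loc[m.taxon_ids, m.taxon_ids]
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rows = []
    for season, frame in frames:
        layers = frame.layers()
        for upper, lower in zip(layers[:-1], layers[1:]):
            su = frame.samples_in_layer(upper)
            sl = frame.samples_in_layer(lower)
            if not su or not sl:
                warnings.warn(f"boundary {upper}|{lower}: layer without samples; skipped",
                              UserWarning, stacklevel=2)
                continue
            c1 = frame.counts[su].sum(axis=1)
            c2 = frame.counts[sl].sum(axis=1)
            s_b, s_r = ss.spawn(2)
            b = bnti(c1, c2, dist, n_null=n_null, seed=s_b, weighted=weighted)
            r = raup_crick_bray(c1, c2, frame, n_null=n_null_rc, seed=s_r)
            rows.append(
                {
                    "season": season,
                    "upper_layer": upper,
                    "lower_layer": lower,
                    "bnti": b,
                    "rc_bray": r,
                    "process": classify_pair(b, r),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["upper_layer", "season"], kind="stable").reset_index(drop=True)
    return out
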