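"""Levin's niche breadth profiling across depth layers.

For a seasonally pooled matrix (one local community per layer), a taxon's
Levin's breadth is the inverse Simpson concentration of its distribution
across the N layers,

    B_j = 1 / sum_i P_ij^2,   P_ij = x_ij / sum_i x_ij,

ranging from 1 (single-layer specialist) to N (uniform generalist). The
mean niche breadth of a local community is the within-layer
abundance-weighted mean

    MNB_i = sum_j Q_ij * B_j,   Q_ij = x_ij / sum_j x_ij,

which therefore lies in [1, N] (a weighted mean of values >= 1 cannot fall
below 1). A second-order OLS polynomial of MNB against layer index
summarises the depth profile; its vertex marks the generalist-rich
transition zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CommunityMatrix

__all__ = ["levins_breadth", "mean_niche_breadth", "fit_mnb_depth", "QuadraticFit"]


def levins_breadth(m: CommunityMatrix) -> pd.Series:
    """Per-taxon Levin's niche breadth B_j across layers.

    Expects a seasonally merged matrix (one sample per layer). Taxa absent
    everywhere are excluded with a warning.
    """
    x = m.counts.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} all-zero taxa from niche breadth", UserWarning,
            stacklevel=2,
        )
    keep = ~zero
    p = x[keep] / totals[keep, None]
    b = 1.0 / (p ** 2).sum(axis=1)
    return pd.Series(b, index=m.counts.index[keep], name="levins_b")


def mean_niche_breadth(m: CommunityMatrix, b: pd.Series | None = None) -> pd.Series:
    """Per-layer mean niche breadth: within-layer abundance-weighted mean of B_j."""
    if b is None:
        b = levins_breadth(m)
    counts = m.counts.loc[b.index]
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        raise ValueError(f"empty layers: {list(sums.index[sums == 0])}")
    q = counts / sums
    mnb = q.mul(b, axis=0).sum(axis=0)
    mnb.name = "mnb"
    return mnb


@dataclass
class QuadraticFit:
    coefficients: np.ndarray  # [c0, c1, c2] for c0 + c1*x + c2*x^2
    r_squared: float
    vertex: float             # layer index at the parabola's extremum


def fit_mnb_depth(mnb: pd.Series, layers=None) -> QuadraticFit:
    """OLS second-order polynomial of MNB against layer index."""
    y = np.asarray(mnb, dtype=float)
    if layers is None:
        x = np.arange(1, len(y) + 1, dtype=float)
    else:
        x = np.asarray(layers, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 layers for the quadratic fit")
    design = np.column_stack([np.ones_like(x), x, x ** 2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    vertex = float(-coef[1] / (2 * coef[2])) if coef[2] != 0 else float("nan")
    return QuadraticFit(coefficients=coef, r_squared=r2, vertex=vertex)
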