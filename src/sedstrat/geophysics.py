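"""Sediment interstitial-space physics and age-depth operations.

A saturated sediment layer holds pore water and solids only; methane
supersaturation below a critical depth adds a free gas phase. With the
volumetric water content ``Moi_v = V_w / V_T`` (water volume over the total
in-situ volume ``V_T = V_w + V_s + V_a``, gas included), the mass water
content ``Moi_m = M_w / M_T`` (water mass over total mass), the pore-water
density ``rho_w`` and the mixed-sediment density measured by the submerged
method ``rho_ws`` (the lab sample is degassed, so
``rho_ws = M_T / (V_w + V_s)``), the gas-space volume fraction of a layer is

    VP_a = 1 - (Moi_v * rho_w) / (Moi_m * rho_ws)

which reduces algebraically to ``V_a / V_T``: the ratio's numerator is
``M_w / V_T`` and its denominator ``M_w / (V_w + V_s)``. The total
interstitial space is ``TIS = Moi_v + VP_a``. Both are volume
fractions of the layer. Measurement noise can push the raw VP_a slightly
negative for saturated layers; such values are clamped to zero and flagged.

The age-depth model is a piecewise-linear interpolation through dated
anchors (depth, calendar year), extended below the deepest anchor at the
terminal segment's constant rate. Mean deposition rates over a depth
interval follow directly as thickness over elapsed years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "gas_volume_percent",
    "total_interstitial_space",
    "interstitial_table",
    "AgeDepthModel",
]

#: required columns of a per-layer physics table
PHYSICS_COLUMNS = ("moi_v", "moi_m", "rho_w", "rho_ws")


def _check_row(moi_v: float, moi_m: float, rho_w: float, rho_ws: float) -> None:
    if not (0.0 < moi_v < 1.0):
        raise ValueError(f"moi_v must lie in (0, 1), got {moi_v}")
    if not (0.0 < moi_m < 1.0):
        raise ValueError(f"moi_m must lie in (0, 1), got {moi_m}")
    if rho_w <= 0 or rho_ws <= 0:
        raise ValueError("densities must be positive")
    if moi_m * rho_ws == 0:
        raise ValueError("moi_m * rho_ws must be nonzero")


def gas_volume_percent(
    moi_v: float, moi_m: float, rho_w: float, rho_ws: float, *, warn: bool = True
) -> float:
    """Gas-space volume fraction VP_a of one sediment layer, in [0, 1].

    Negative raw values (a physically saturated layer measured with noise)
    clamp to 0.0; a ``UserWarning`` is emitted unless ``warn=False``. Raw
    values above 1 cannot arise from positive inputs and raise.
    """
    _check_row(moi_v, moi_m, rho_w, rho_ws)
    raw = 1.0 - (moi_v * rho_w) / (moi_m * rho_ws)
    if raw > 1.0:
        raise ValueError(f"gas volume fraction {raw} > 1 is unphysical")
    if raw < 0.0:
        if warn:
            warnings.warn(
                f"raw gas volume fraction {raw:.4g} < 0; clamped to 0", UserWarning, stacklevel=2
            )
        return 0.0
    return raw


def total_interstitial_space(
    moi_v: float, moi_m: float, rho_w: float, rho_ws: float, *, warn: bool = True
) -> float:
    """Total interstitial space TIS = Moi_v + VP_a (volume fraction)."""
    tis = moi_v + gas_volume_percent(moi_v, moi_m, rho_w, rho_ws, warn=warn)
    if tis > 1.0 + 1e-12:
        raise ValueError(f"TIS {tis} > 1 is unphysical")
    return min(tis, 1.0)


def interstitial_table(physics: pd.DataFrame) -> pd.DataFrame:
    """Vectorised VP_a / TIS over a physics table.

    ``physics`` needs columns ``moi_v, moi_m, rho_w, rho_ws``; any other
    columns (layer, season, temp, ...) are carried through. The result adds
    ``vp_raw`` (unclamped), ``vp_a``, ``tis`` and a boolean ``warning``
    column flagging rows whose raw VP_a fell outside [0, 1].
    """
    for col in PHYSICS_COLUMNS:
        if col not in physics.columns:
            raise ValueError(f"physics table lacks column {col!r}")
    out = physics.copy()
    vp_raw = np.empty(len(out))
    vp = np.empty(len(out))
    flags = np.zeros(len(out), dtype=bool)
    for i, (_, row) in enumerate(out.iterrows()):
        _check_row(row["moi_v"], row["moi_m"], row["rho_w"], row["rho_ws"])
        raw = 1.0 - (row["moi_v"] * row["rho_w"]) / (row["moi_m"] * row["rho_ws"])
        vp_raw[i] = raw
        flags[i] = raw < 0.0 or raw > 1.0
        vp[i] = gas_volume_percent(
            row["moi_v"], row["moi_m"], row["rho_w"], row["rho_ws"], warn=False
        )
    out["vp_raw"] = vp_raw
    out["vp_a"] = vp
    out["tis"] = out["moi_v"] + vp
    out["warning"] = flags
    return out


# ----------------------------------------------------------------------
@dataclass
class AgeDepthModel:
    """Piecewise-linear age-depth model through dated anchors.

    ``anchors`` is a sequence of (depth_cm, calendar_year) pairs including
    the surface anchor; depths must be strictly increasing and years
    strictly decreasing. Depths below the deepest anchor extrapolate at the
    terminal segment's rate.
    """

    anchors: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.anchors = [(float(d), float(y)) for d, y in self.anchors]
        self.anchors.sort(key=lambda a: a[0])
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchors")
        depths = np.array([a[0] for a in self.anchors])
        years = np.array([a[1] for a in self.anchors])
        if not (np.diff(depths) > 0).all():
            raise ValueError("anchor depths must be strictly increasing")
        if not (np.diff(years) < 0).all():
            raise ValueError("anchor years must be strictly decreasing with depth")
        self._depths = depths
        self._years = years

    # ------------------------------------------------------------------
    def depth_to_year(self, depth: float) -> float:
        """Calendar year of the sediment at ``depth`` cm below the surface."""
        if depth < 0:
            raise ValueError("depth must be non-negative")
        d, y = self._depths, self._years
        if depth > d[-1]:
            slope = (y[-1] - y[-2]) / (d[-1] - d[-2])  # yr per cm, negative
            return y[-1] + slope * (depth - d[-1])
        return float(np.interp(depth, d, y))

    def year_to_depth(self, year: float) -> float:
        """Inverse of :meth:`depth_to_year` (years within the model span)."""
        d, y = self._depths, self._years
        if year > y[0]:
            raise ValueError(f"year {year} postdates the surface anchor {y[0]}")
        if year < y[-1]:
            slope = (y[-1] - y[-2]) / (d[-1] - d[-2])
            return d[-1] + (year - y[-1]) / slope
        # years decrease with depth: interpolate on reversed arrays
        return float(np.interp(year, y[::-1], d[::-1]))

    def deposition_rate(self, depth_top: float, depth_bottom: float) -> float:
        """Mean deposition rate (cm/year) over [depth_top, depth_bottom]."""
        if not depth_top < depth_bottom:
            raise ValueError("depth_top must be shallower than depth_bottom")
        dy = self.depth_to_year(depth_top) - self.depth_to_year(depth_bottom)
        if dy == 0:
            raise ValueError("zero year difference over the segment")
        return (depth_bottom - depth_top) / dy

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        pd.DataFrame(self.anchors, columns=["depth_cm", "year"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "AgeDepthModel":
        df = pd.read_csv(path, sep="\t")
        return cls(list(zip(df["depth_cm"], df["year"])))
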