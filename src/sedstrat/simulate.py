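"""Synthetic stratified-sediment dataset generator.

Emulates the processed structure of a dammed-lake sediment survey: ~11
depth layers sampled over 6 bimonthly seasons (5-cm intervals), a
compositional regime shift at a "damming horizon" layer, gradient turnover
above/below it, seasonal noise, a per-layer physics table (saturated above
the horizon, positive gas fraction below), and dated age-depth anchors.
Assembly regimes are planted per zone so downstream null-model inference
has a ground truth:

* ``selection`` — taxa respond to a depth-indexed environmental variable E
  through Gaussian niche curves; niche optima are conserved on the tree at
  the clade level (the tree is cut into clades, each clade inherits an
  optimum centre, tips jitter around it), so environmental filtering is
  phylogenetically structured: a layer gaining or losing a clade moves its
  betaMNTD away from the tip-shuffling null. E increases by 1 per layer
  and takes a step of ``effect_size`` at the damming horizon.
* ``neutral`` — flat responses; layer expectations equal the lognormal
  species-abundance distribution, independent of depth and phylogeny.
* ``dispersal_limited`` — a layer-to-layer compositional random walk with
  no environmental term: each layer's expected composition multiplies the
  previous one by lognormal noise and loses a small fraction of taxa to
  local extinction, producing turnover that is stronger than the
  metacommunity null but carries no phylogenetic signal.

Every layer expectation is additionally mixed with a small mass-effect
contribution from the regional pool (the SAD), emulating source-sink
dispersal and keeping dissimilarities off their ceiling. Counts are
multinomial draws at a fixed library size per (layer, season) sample after
lognormal seasonal jitter of the layer expectation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim

from .containers import CommunityMatrix
from .geophysics import AgeDepthModel
from .trees import clade_groups, patristic_matrix, write_tree

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate_tree", "generate_dataset"]

REGIMES = ("selection", "neutral", "dispersal_limited")

#: calendar year of the surface anchor and of the damming horizon
SURFACE_YEAR = 2015.0
DAMMING_YEAR = 1963.0
#: deposition rate (cm/yr) assumed below the horizon when building anchors
PRE_DAMMING_RATE = 0.13


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic stratified-sediment generator.

    Defaults mirror the emulated survey design: 11 layers x 6 seasons of
    5-cm intervals with the damming horizon in layer 5, selection-driven
    assembly above it and dispersal-limited assembly below, and a 50,000
    read library per sample.
    """

    n_taxa: int
    n_layers: int = 11
    n_seasons: int = 6
    damming_layer: int = 5
    regime_above: str = "selection"
    regime_below: str = "dispersal_limited"
    niche_width: float = 0.5
    effect_size: float = 4.0
    seasonal_noise: float = 0.5
    walk_sigma: float = 1.2
    walk_extinction: float = 0.05
    sad_sigma: float = 1.0
    pool_mixing: float = 0.0
    niche_truncation: float = 2.5
    generalist_fraction: float = 0.4
    generalist_width_factor: float = 4.0
    library_size: int = 50_000
    depth_per_layer: float = 5.0
    dropout: tuple = ()  # (layer, season_index) pairs to omit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_layers < 2 or self.n_seasons < 1:
            raise ValueError("n_taxa and n_layers must be >= 2, n_seasons >= 1")
        if not 1 <= self.damming_layer <= self.n_layers:
            raise ValueError("damming_layer must lie in [1, n_layers]")
        for name in ("niche_width", "effect_size", "walk_sigma", "sad_sigma",
                     "depth_per_layer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seasonal_noise < 0:
            raise ValueError("seasonal_noise must be non-negative")
        if not 0 <= self.walk_extinction < 1:
            raise ValueError("walk_extinction must lie in [0, 1)")
        if not 0 <= self.pool_mixing < 1:
            raise ValueError("pool_mixing must lie in [0, 1)")
        if not 0 <= self.generalist_fraction <= 1:
            raise ValueError("generalist_fraction must lie in [0, 1]")
        if self.generalist_width_factor < 1:
            raise ValueError("generalist_width_factor must be >= 1")
        for regime in (self.regime_above, self.regime_below):
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["dropout"] = tuple(tuple(x) for x in raw.get("dropout", ()))
        return cls(**raw)


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    tree: dendropy.Tree
    counts: CommunityMatrix
    physics: pd.DataFrame
    age_anchors: AgeDepthModel
    truth: pd.DataFrame           # per adjacent-layer pair: zone, regime, expected process
    taxonomy: pd.DataFrame        # clade-derived phylum/class labels per taxon
    config: GeneratorConfig
    optima: pd.Series = field(default=None, repr=False)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_tree(self.tree, out / "tree.nwk")
        self.counts.to_tsv(out / "counts.tsv", out / "sample_meta.tsv")
        self.physics.to_csv(out / "physics.tsv", sep="\t", index=False)
        self.age_anchors.to_tsv(out / "age_anchors.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index_label="taxon_id")
        self.config.to_yaml(out / "config.yaml")


# ----------------------------------------------------------------------
def generate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random rooted bifurcating tree with positive branch lengths.

    Kingman-coalescent topology; tips are labelled ``OTU_0001`` ... in
    namespace order. Deterministic under ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    labels = [f"OTU_{i:04d}" for i in range(1, n_taxa + 1)]
    tns = dendropy.TaxonNamespace(labels)
    tree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0,
                                     rng=random.Random(int(seed)))
    # guard against numerically zero internal edges
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.head_node.parent_node is not None:
            edge.length = max(float(edge.length), 1e-9)
    return tree


def _clade_niches(
    dist: pd.DataFrame, e: np.ndarray, config: GeneratorConfig,
    rng: np.random.Generator, jitter: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Clade-conserved niche optima and widths.

    The tree is cut into roughly ten-tip clades and every clade is assigned
    one niche guild, so the trait is conserved at the clade level — losing
    a clade between two layers removes a phylogenetically coherent block of
    taxa, which is what a betaMNTD null registers as selection. Guilds:

    * specialist clades (1 - generalist_fraction): optimum centred on the
      E value of a random layer, tolerance ``niche_width`` — a narrow
      depth band;
    * zone generalists: centred mid-zone (above or below the horizon) with
      ``generalist_width_factor`` x broader tolerance — present throughout
      their zone, bounding within-zone dissimilarity;
    * ecotone generalists (one fifth of generalist clades): centred on the
      horizon step midpoint with very broad tolerance — taxa spanning both
      sides of the transition, which is what puts the mean-niche-breadth
      peak at the damming horizon.

    Tip optima jitter around their clade centre. Returns (optima, widths).
    """
    n = dist.shape[0]
    k = int(np.clip(n // 10, 4, 24))
    groups = clade_groups(dist, k)
    codes = pd.Categorical(groups).codes
    k_eff = codes.max() + 1
    e_above = e[: config.damming_layer - 1]
    e_below = e[config.damming_layer - 1:]
    e_mid = (e_above.max() + e_below.min()) / 2 if len(e_above) else float(np.median(e))

    centres = np.empty(k_eff)
    widths_c = np.full(k_eff, config.niche_width)
    gw = config.niche_width * config.generalist_width_factor
    u = rng.random(k_eff)
    for c in range(k_eff):
        if u[c] < config.generalist_fraction:
            guild = rng.random()
            if guild < 0.2:  # ecotone generalist
                centres[c] = e_mid
                widths_c[c] = gw * 1.5
            elif guild < 0.6 and len(e_above):  # above-zone generalist
                centres[c] = e_above.mean()
                widths_c[c] = gw
            else:  # below-zone generalist
                centres[c] = e_below.mean()
                widths_c[c] = gw
        else:  # specialist: a narrow band at a random layer
            centres[c] = rng.choice(e)
    optima = centres[codes] + rng.normal(0.0, jitter, n)
    return optima, widths_c[codes]


def _environment(config: GeneratorConfig) -> np.ndarray:
    """Depth-indexed environmental variable: unit gradient + horizon step."""
    layers = np.arange(1, config.n_layers + 1, dtype=float)
    return layers + config.effect_size * (layers >= config.damming_layer)


def _expected_process(regime: str) -> str:
    return {
        "selection": "heterogeneous_selection",
        "neutral": "drift",
        "dispersal_limited": "dispersal_limitation",
    }[regime]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate one synthetic dataset (bit-identical under config + seed)."""
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_optima, s_sad, s_walk, s_counts, s_phys = ss.spawn(6)
    tree = generate_tree(config.n_taxa, int(np.random.default_rng(s_tree).integers(2 ** 31)))
    taxa = [t.label for t in tree.taxon_namespace]

    # lognormal species-abundance distribution (metacommunity weights)
    sad = np.exp(np.random.default_rng(s_sad).normal(0.0, config.sad_sigma, config.n_taxa))

    # clade-conserved niche optima and tolerances (specialist/generalist guilds)
    e = _environment(config)
    dist = patristic_matrix(tree)
    optima, widths = _clade_niches(dist, e, config, np.random.default_rng(s_optima))

    # layer expectation matrix (taxa x layers)
    w = np.zeros((config.n_taxa, config.n_layers))
    walk_rng = np.random.default_rng(s_walk)
    zones = [
        (range(0, config.damming_layer - 1), config.regime_above),
        (range(config.damming_layer - 1, config.n_layers), config.regime_below),
    ]
    for layer_range, regime in zones:
        layer_list = list(layer_range)
        if not layer_list:
            continue
        if regime == "selection":
            for li in layer_list:
                dev = np.abs(e[li] - optima)
                resp = np.exp(-(dev ** 2) / (2.0 * widths ** 2))
                # hard tolerance limit: outside ~2.5 niche widths a taxon is
                # truly absent, so presence/absence carries the filtering
                # signal instead of vanishing tail frequencies
                resp[dev > config.niche_truncation * widths] = 0.0
                if not resp.any():  # sparse trees: keep the closest taxa alive
                    resp = np.exp(-(dev ** 2) / (2.0 * widths ** 2))
                w[:, li] = sad * resp
        elif regime == "neutral":
            for li in layer_list:
                w[:, li] = sad
        else:  # dispersal_limited: compositional random walk from the SAD
            v = sad.copy()
            for li in layer_list:
                v = v * np.exp(walk_rng.normal(0.0, config.walk_sigma, config.n_taxa))
                v[walk_rng.random(config.n_taxa) < config.walk_extinction] = 0.0
                if (v > 0).sum() < 2:  # keep at least two taxa alive
                    v = sad.copy()
                w[:, li] = v
    # mass effect: mix in a small regional-pool contribution per layer
    w = w / w.sum(axis=0, keepdims=True)
    pool = sad / sad.sum()
    w = (1.0 - config.pool_mixing) * w + config.pool_mixing * pool[:, None]

    # seasonal samples: lognormal jitter of the layer expectation + multinomial
    count_rng = np.random.default_rng(s_counts)
    cols, meta_rows = {}, []
    for li in range(config.n_layers):
        for si in range(config.n_seasons):
            if (li + 1, si + 1) in {tuple(d) for d in config.dropout}:
                continue
            p = w[:, li] * np.exp(count_rng.normal(0.0, config.seasonal_noise, config.n_taxa))
            p = p / p.sum()
            name = f"L{li + 1:02d}S{si + 1}"
            cols[name] = count_rng.multinomial(config.library_size, p)
            meta_rows.append({"sample_id": name, "layer": li + 1, "season": f"S{si + 1}"})
    counts = CommunityMatrix(
        pd.DataFrame(cols, index=taxa),
        pd.DataFrame(meta_rows).set_index("sample_id"),
    )

    physics, gas_truth = _physics_table(config, np.random.default_rng(s_phys))
    anchors = _age_anchors(config)
    truth = _truth_table(config, gas_truth)
    taxonomy = pd.DataFrame(
        {
            "phylum": clade_groups(dist, max(2, min(15, config.n_taxa // 10 or 2)), "Phylum"),
            "class": clade_groups(dist, max(2, min(30, config.n_taxa // 5 or 2)), "Class"),
        }
    )
    return SyntheticDataset(
        tree=tree, counts=counts, physics=physics, age_anchors=anchors,
        truth=truth, taxonomy=taxonomy, config=config,
        optima=pd.Series(optima, index=taxa, name="niche_optimum"),
    )


# ----------------------------------------------------------------------
def _physics_table(config: GeneratorConfig, rng: np.random.Generator):
    """Per-(layer, season) physics built from first-principles volume
    fractions, so the planted gas fraction is exactly recoverable."""
    rho_w, rho_s = 1.0, 2.65
    rows, gas = [], {}
    for li in range(1, config.n_layers + 1):
        below = li >= config.damming_layer
        for si in range(1, config.n_seasons + 1):
            if below:
                v_a = float(np.clip(0.05 + rng.normal(0.0, 0.01), 0.01, 0.12))
                v_w = float(np.clip(0.60 - v_a + rng.normal(0.0, 0.02), 0.3, 0.9))
            else:
                v_a = 0.0
                v_w = float(np.clip(0.85 - 0.03 * (li - 1) + rng.normal(0.0, 0.02),
                                    0.3, 0.95))
            v_s = 1.0 - v_w - v_a
            m_w, m_s = v_w * rho_w, v_s * rho_s
            rows.append(
                {
                    "layer": li,
                    "season": f"S{si}",
                    "moi_v": v_w,  # in situ, over total volume incl. gas (V_T = 1)
                    "moi_m": m_w / (m_w + m_s),
                    "rho_w": rho_w,
                    # submerged-method bulk density: the lab sample is degassed,
                    # so the volume excludes the gas phase
                    "rho_ws": (m_w + m_s) / (v_w + v_s),
                    "temp_c": 16.0 + 8.0 * np.exp(-0.3 * (li - 1))
                    * np.sin(2 * np.pi * si / config.n_seasons),
                    "orp_mv": 150.0 - 60.0 * np.log1p(li) + rng.normal(0.0, 10.0),
                    "toc_pct": (1.8 if not below else 1.1) + rng.normal(0.0, 0.1),
                }
            )
        gas[li] = 0.0 if not below else 0.05
    physics = pd.DataFrame(rows)
    return physics, gas


def _age_anchors(config: GeneratorConfig) -> AgeDepthModel:
    """Three anchors: surface, mid-damming-layer horizon, core bottom."""
    d_dam = (config.damming_layer - 0.5) * config.depth_per_layer
    d_bot = config.n_layers * config.depth_per_layer
    y_bot = DAMMING_YEAR - (d_bot - d_dam) / PRE_DAMMING_RATE
    return AgeDepthModel([(0.0, SURFACE_YEAR), (d_dam, DAMMING_YEAR), (d_bot, y_bot)])


def _truth_table(config: GeneratorConfig, gas: dict) -> pd.DataFrame:
    rows = []
    for upper in range(1, config.n_layers):
        lower = upper + 1
        if lower < config.damming_layer:
            zone, regime = "above", config.regime_above
        elif upper >= config.damming_layer:
            zone, regime = "below", config.regime_below
        else:
            zone = "crossing"
            regime = (config.regime_above
                      if config.regime_above == "selection" or
                      config.regime_below == "selection"
                      else config.regime_below)
            if "selection" in (config.regime_above, config.regime_below):
                regime = "selection"
        rows.append(
            {
                "upper_layer": upper,
                "lower_layer": lower,
                "zone": zone,
                "regime": regime,
                "expected_process": _expected_process(regime),
                "gas_fraction_lower": gas[lower],
            }
        )
    return pd.DataFrame(rows)
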