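"""End-to-end orchestration: ingest or simulate, then run every stage.

Stages: input validation -> interstitial-space physics -> community
structure (rarefaction, alpha, dissimilarity, PCoA, UPGMA + ANOSIM,
per-layer temporal fluctuation, connection degree) -> null-model assembly
partition and adjacent-layer betaNTI profile -> niche breadth profile ->
random-forest damming-sensitivity screen. All stage outputs land in the
run directory as TSV, with a machine-readable ``summary.json`` and a
``provenance.yaml`` recording versions, seeds and parameters so a rerun
reproduces every stochastic stage bit-identically.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community as comm
from . import niche as niche_mod
from . import phylo_null as pn
from . import sensitivity as sens
from .containers import CommunityMatrix
from .geophysics import AgeDepthModel, interstitial_table
from .simulate import GeneratorConfig, SyntheticDataset, generate_dataset
from .trees import check_tips_cover, read_tree

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``generator`` (a :class:`GeneratorConfig`) or
    ``input_paths`` (dict with keys counts, metadata, tree and optionally
    physics, age_anchors, taxonomy) must be set.
    """

    outdir: str
    generator: GeneratorConfig | None = None
    input_paths: dict | None = None
    rarefy: bool = True
    n_null_bnti: int = 999
    n_null_rc: int = 999
    n_perm: int = 999
    n_forests: int = 100
    n_trees: int = 1000
    max_breaks: int = 3
    feature_rank: str = "phylum"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_paths is None):
            raise ValueError("set exactly one of generator / input_paths")


def _load_inputs(paths: dict):
    cm = CommunityMatrix.from_tsv(paths["counts"], paths.get("metadata"))
    tree = read_tree(paths["tree"])
    physics = (pd.read_csv(paths["physics"], sep="\t")
               if paths.get("physics") else None)
    anchors = (AgeDepthModel.from_tsv(paths["age_anchors"])
               if paths.get("age_anchors") else None)
    taxonomy = (pd.read_csv(paths["taxonomy"], sep="\t", index_col=0)
                if paths.get("taxonomy") else None)
    return cm, tree, physics, anchors, taxonomy


def validate_inputs(cm: CommunityMatrix, tree, physics: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """Cross-input consistency checks; failures are report rows, not errors."""
    checks = []

    def add(name: str, ok: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(ok), "detail": detail})

    arr = cm.counts.to_numpy()
    add("counts_integral", bool(np.allclose(arr, np.round(arr))))
    add("counts_nonnegative", bool((arr >= 0).all()))
    try:
        check_tips_cover(tree, cm.taxon_ids)
        add("tree_taxon_concordance", True)
    except ValueError as exc:
        add("tree_taxon_concordance", False, str(exc))
    meta = cm.sample_meta
    add("metadata_complete",
        set(cm.sample_ids) <= set(meta.index) and not meta.loc[cm.sample_ids].isna().any().any())
    if physics is not None:
        ok = True
        detail = ""
        for col in ("moi_v", "moi_m"):
            if col not in physics.columns:
                ok, detail = False, f"missing column {col}"
                break
            vals = physics[col].to_numpy(dtype=float)
            if not ((vals > 0) & (vals < 1)).all():
                ok, detail = False, f"{col} outside (0, 1)"
                break
        add("physics_ranges", ok, detail)
    return pd.DataFrame(checks)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_rarefy, s_anosim, s_assembly, s_profile, s_rf, s_urf = ss.spawn(6)

    dataset: SyntheticDataset | None = None
    taxonomy = None
    if config.generator is not None:
        dataset = generate_dataset(config.generator)
        dataset.write(out / "inputs")
        cm, tree = dataset.counts, dataset.tree
        physics, anchors, taxonomy = dataset.physics, dataset.age_anchors, dataset.taxonomy
    else:
        cm, tree, physics, anchors, taxonomy = _load_inputs(config.input_paths)

    report = validate_inputs(cm, tree, physics)
    report.to_csv(out / "validation.tsv", sep="\t", index=False)
    if not report["passed"].all():
        failed = list(report.loc[~report["passed"], "check"])
        raise ValueError(f"input validation failed: {failed}")

    summary: dict = {"version": __version__}

    # ---- geophysics -------------------------------------------------
    if physics is not None:
        phys = interstitial_table(physics)
        phys.to_csv(out / "physics_interstitial.tsv", sep="\t", index=False)
        per_layer = phys.groupby("layer")[["vp_a", "tis"]].mean()
        summary["physics"] = {
            "mean_vp_a_per_layer": per_layer["vp_a"].round(6).to_dict(),
            "mean_tis_per_layer": per_layer["tis"].round(6).to_dict(),
        }
    if anchors is not None:
        depths = [a[0] for a in anchors.anchors]
        mid = depths[len(depths) // 2]
        summary["age_depth"] = {
            "anchors": anchors.anchors,
            "rate_upper_cm_per_yr": anchors.deposition_rate(depths[0], mid),
            "rate_lower_cm_per_yr": anchors.deposition_rate(mid, depths[-1]),
        }

    # ---- community structure ---------------------------------------
    work = comm.rarefy(cm, "min", seed=int(np.random.default_rng(s_rarefy).integers(2 ** 31))
                       ) if config.rarefy else cm
    alpha = comm.alpha_diversity(work)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    bc = comm.dissimilarity(work, "bray_curtis")
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")
    comm.dissimilarity(work, "jaccard_binary").to_csv(out / "jaccard.tsv", sep="\t")
    ord_res = comm.pcoa(bc, k=2)
    ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")

    merged = comm.merge_seasons(work)
    bc_merged = comm.dissimilarity(merged, "bray_curtis")
    dendro = comm.upgma(bc_merged)
    split = dendro.cut(2)
    split.to_csv(out / "upgma_k2.tsv", sep="\t", header=True)

    meta = work.sample_meta.loc[work.sample_ids]
    horizon = (config.generator.damming_layer if config.generator is not None
               else int(np.median(meta["layer"])))
    zone = np.where(meta["layer"] < horizon, "above", "below")
    r_stat, p_val = comm.anosim(bc, pd.Series(zone, index=bc.index),
                                n_perm=config.n_perm,
                                seed=int(np.random.default_rng(s_anosim).integers(2 ** 31)))
    fluct_rows = []
    for layer in work.layers():
        samples = work.samples_in_layer(layer)
        if len(samples) < 2:
            continue
        parts = comm.multi_timepoint_dissimilarity(work.subset_samples(samples))
        fluct_rows.append({"layer": layer, **parts})
    fluct = pd.DataFrame(fluct_rows)
    fluct.to_csv(out / "temporal_fluctuation.tsv", sep="\t", index=False)
    degree = comm.connection_degree(merged)
    degree.to_csv(out / "connection_degree.tsv", sep="\t", header=True)

    summary["community"] = {
        "n_samples": work.n_samples,
        "rarefaction_depth": int(work.sample_sums().iloc[0]),
        "anosim_r": r_stat,
        "anosim_p": p_val,
        "upgma_k2": split.to_dict(),
        "pcoa_proportion_explained": [float(x) for x in ord_res.proportion_explained],
    }

    # ---- assembly processes ----------------------------------------
    profile = pn.adjacent_layer_profile(
        work, tree, mode="merged", n_null=config.n_null_bnti,
        n_null_rc=config.n_null_rc, seed=s_profile,
    )
    profile.to_csv(out / "adjacent_bnti_profile.tsv", sep="\t", index=False)
    res = pn.assembly_analysis(
        merged, tree, n_null=config.n_null_bnti, n_null_rc=config.n_null_rc,
        seed=s_assembly,
    )
    res.to_frame().to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
    pd.Series(res.fractions).to_csv(out / "assembly_fractions.tsv", sep="\t", header=True)
    summary["assembly"] = {
        "fractions": res.fractions,
        "boundary_bnti": profile["bnti"].tolist(),
        "boundary_process": profile["process"].tolist(),
    }

    # ---- niche breadth ----------------------------------------------
    b = niche_mod.levins_breadth(merged)
    b.to_csv(out / "levins_breadth.tsv", sep="\t", header=True)
    mnb = niche_mod.mean_niche_breadth(merged, b)
    mnb.to_csv(out / "mean_niche_breadth.tsv", sep="\t", header=True)
    fit = niche_mod.fit_mnb_depth(mnb, layers=merged.layers())
    summary["niche"] = {
        "mnb": mnb.round(4).to_dict(),
        "fit_coefficients": [float(c) for c in fit.coefficients],
        "fit_r_squared": fit.r_squared,
        "fit_vertex_layer": fit.vertex,
    }

    # ---- damming sensitivity ---------------------------------------
    rel = work.relative_abundance().T  # samples x taxa
    if taxonomy is not None and config.feature_rank in getattr(taxonomy, "columns", []):
        groups = taxonomy.loc[rel.columns, config.feature_rank]
        rel = rel.T.groupby(groups).sum().T
    labels = np.where(meta["layer"] < horizon, "post_damming", "pre_damming")
    ranking = sens.rf_importance_ensemble(
        rel, labels, n_forests=config.n_forests, n_trees=config.n_trees, seed=s_rf,
    )
    n_feat = rel.shape[1]
    eff_breaks = min(config.max_breaks, max(1, (n_feat - 1) // 2))
    if n_feat >= 4 and eff_breaks < n_feat / 2:
        ranking = sens.importance_breakpoints(ranking, max_breaks=eff_breaks)
    ranking.table.to_csv(out / "importance_ranking.tsv", sep="\t", index=False)
    clust = sens.unsupervised_rf_clustering(rel, n_trees=config.n_trees, seed=s_urf)
    clust.proximity.to_csv(out / "rf_proximity.tsv", sep="\t")
    clust.coordinates.to_csv(out / "rf_scaling_coordinates.tsv", sep="\t")
    summary["sensitivity"] = {
        "oob_error": ranking.oob_error,
        "selected_taxa": ranking.selected_taxa,
        "breakpoints": ranking.breakpoints,
        "unsupervised_k2": clust.clusters.to_dict(),
    }

    # ---- provenance + summary ---------------------------------------
    provenance = {
        "sedstrat_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("generator", "input_paths")
        },
        "generator": asdict(config.generator) if config.generator is not None else None,
        "input_paths": dict(config.input_paths) if config.input_paths else None,
    }
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
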