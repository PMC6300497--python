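"""End-to-end orchestration: from a genotype table (or a synthetic study)
to distance matrices, clone partitions, diversity tables, ordination, trees,
parentage rankings and cytotype summaries, with a manifest recording every
parameter and seed.

Stage order::

    read/simulate -> distances (per locus subset) -> MLGs -> histogram +
    threshold -> clonal lineages -> diversity table -> PCoA + NJ ->
    parentage (two pool modes) -> cytotype table

Analyses that mix diploids and polyploids run on the *core* locus subset
(the loci that amplify in every taxon); polyploid-only analyses (clone
threshold, lineages, the second diversity column) use the full panel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bruvo, clonal, parentage, ploidy, structure, synth
from .genotype_io import (
    GenotypeSet,
    read_genotype_table,
    read_locus_panel,
    write_distance_matrix,
    write_genotype_table,
    write_locus_panel,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("apoclone")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML-serialisable via ``from_dict``."""

    out_dir: str = "apoclone_out"
    # inputs; all None -> simulate a synthetic study instead
    genotype_csv: str | None = None
    panel_csv: str | None = None
    fcm_csv: str | None = None
    genotype_units: str = "repeats"
    # model choices
    bruvo_model: str = "combined"
    simpson_unbiased: bool = True
    threshold_override: float | None = None
    bin_width: float = 0.01
    core_loci: list[str] | None = None  # None -> loci scored in every taxon
    rarefaction_reps: int = 1000
    rarefy: dict | None = None  # {"taxon": ..., "n": ...}
    variable_loci: list[str] = field(default_factory=list)
    allow_self_pairs: bool = False
    # ploidy stage
    diploid_ref_taxon: str | None = None  # None -> mean 2C of diploid records
    ploidy_tolerance: float = 0.25
    base_x: int = ploidy.SORBUS_BASE_X
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _infer_core_loci(gs: GenotypeSet) -> list[str]:
    """Loci scored in at least one sample of every taxon."""
    taxa = gs.taxa()
    core = []
    for l in gs.locus_names:
        if all(
            any(g.alleles.get(l) for g in gs.subset_taxa([t]).genotypes)
            for t in taxa
        ):
            core.append(l)
    return core


def _polyploid_taxa(gs: GenotypeSet) -> list[str]:
    return [
        t
        for t in gs.taxa()
        if any(g.ploidy and g.ploidy > 2 for g in gs.subset_taxa([t]).genotypes)
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON).

    A stage failure raises with the stage named; outputs of completed stages
    are left in place.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": {k: v for k, v in vars(cfg).items()}}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    def fail(name: str, err: Exception):
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    # -- stage: read / simulate ------------------------------------------
    stage("input")
    try:
        if cfg.genotype_csv is None:
            sim_cfg = synth.study_config(seed=cfg.seed)
            gs, fcm_records, truth = synth.simulate_study(sim_cfg)
            write_genotype_table(gs, out / "genotypes.csv")
            write_locus_panel(gs.panel, out / "panel.csv")
            ploidy.write_fcm_csv(fcm_records, out / "fcm.csv")
            (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
            manifest["simulated"] = True
        else:
            if cfg.panel_csv is None:
                raise ValueError("panel_csv is required with genotype_csv")
            panel = read_locus_panel(cfg.panel_csv)
            gs = read_genotype_table(cfg.genotype_csv, panel, units=cfg.genotype_units)
            fcm_records = ploidy.read_fcm_csv(cfg.fcm_csv) if cfg.fcm_csv else []
            manifest["simulated"] = False
    except Exception as e:  # noqa: BLE001
        fail("input", e)
    manifest["n_samples"] = len(gs.genotypes)
    manifest["taxa"] = gs.taxa()

    core = cfg.core_loci or _infer_core_loci(gs)
    manifest["core_loci"] = core
    manifest["all_loci"] = gs.locus_names
    poly_taxa = _polyploid_taxa(gs)
    manifest["polyploid_taxa"] = poly_taxa

    # -- stage: distances -------------------------------------------------
    stage("distances")
    try:
        dm_core = bruvo.distance_matrix(gs, cfg.bruvo_model, loci=core)
        write_distance_matrix(dm_core, out / "distances_core.csv")
        poly = gs.subset_taxa(poly_taxa)
        dm_poly = bruvo.distance_matrix(poly, cfg.bruvo_model)
        write_distance_matrix(dm_poly, out / "distances_polyploid.csv")
    except Exception as e:  # noqa: BLE001
        fail("distances", e)

    # -- stage: MLGs -------------------------------------------------------
    stage("mlgs")
    mlg_core = clonal.assign_mlgs(dm_core)
    mlg_poly = clonal.assign_mlgs(dm_poly)
    manifest["n_mlgs_core"] = mlg_core.n_groups

    # -- stage: histogram + threshold -------------------------------------
    stage("histogram")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hist = clonal.histogram_and_threshold(dm_poly, cfg.bin_width)
    hist.to_frame().to_csv(out / "histogram.csv", index=False)
    _plot_histogram(hist, out / "histogram.png")
    threshold = (
        cfg.threshold_override
        if cfg.threshold_override is not None
        else hist.detected_threshold
    )
    if threshold is None:
        fail("histogram", ValueError("no threshold detected and no override given"))
    manifest["detected_threshold"] = hist.detected_threshold
    manifest["threshold_used"] = threshold
    manifest["n_pairwise_comparisons"] = hist.n_comparisons
    log.info("clone threshold: %s (override=%s)", threshold, cfg.threshold_override)

    # -- stage: clonal lineages -------------------------------------------
    stage("lineages")
    lineages = clonal.assign_clonal_lineages(dm_poly, threshold)
    parts = mlg_core.to_frame().rename(columns={"group": "mlg_id"})
    lin_map = lineages.group_of
    parts["lineage_id"] = [lin_map.get(s, -1) for s in parts["sample_id"]]
    parts.to_csv(out / "partitions.csv", index=False)

    # -- stage: diversity --------------------------------------------------
    stage("diversity")
    try:
        div = clonal.diversity_table(
            gs, mlg_core, lineages, loci=core, unbiased=cfg.simpson_unbiased
        ).rename(columns={"simpson_complement": "simpson_core"})
        # full-panel diversity column for polyploid taxa
        full_col = []
        for t in div["taxon"]:
            if t in poly_taxa:
                sub_ids = gs.subset_taxa([t]).sample_ids
                sizes = clonal.assign_mlgs(dm_poly.subset(sub_ids)).sizes()
                full_col.append(
                    clonal.simpson_complement(sizes, unbiased=cfg.simpson_unbiased)
                    if len(sub_ids) >= 2
                    else np.nan
                )
            else:
                full_col.append(np.nan)
        div["simpson_full"] = full_col
        if cfg.rarefy:
            t, n = cfg.rarefy["taxon"], int(cfg.rarefy["n"])
            div.loc[div["taxon"] == t, "A_rarefied"] = clonal.rarefied_richness(
                gs, t, n, reps=cfg.rarefaction_reps, seed=cfg.seed, loci=core
            )
        div.to_csv(out / "diversity.csv", index=False)
    except Exception as e:  # noqa: BLE001
        fail("diversity", e)

    # -- stage: ordination + tree -----------------------------------------
    stage("ordination")
    try:
        reps = mlg_core.representatives
        dm_reps = dm_core.subset(reps)
        pc = structure.pcoa(dm_reps)
        pc.to_frame().to_csv(out / "coords.csv")
        pd.DataFrame(
            {"eigenvalue": pc.eigenvalues}
        ).to_csv(out / "scree.csv", index=False)
        tree = structure.neighbor_joining(dm_reps)
        structure.write_newick(tree, out / "tree.nwk")
        manifest["pcoa_pct_axis12"] = [float(x) for x in pc.percent_variance[:2]]
    except Exception as e:  # noqa: BLE001
        fail("ordination", e)

    # -- stage: parentage --------------------------------------------------
    stage("parentage")
    try:
        tables = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for mode in ("majority_mlg", "majority_plus_minority"):
                pools = {}
                for t in gs.taxa():
                    src = "all_samples" if t not in poly_taxa else mode
                    pools[t] = parentage.build_pool(
                        gs, t, src, variable_loci=tuple(cfg.variable_loci)
                    )
                for t in poly_taxa:
                    target = parentage.majority_genotype(gs, t)
                    cand = {k: v for k, v in pools.items() if k != t}
                    tab = parentage.rank_parent_pairs(
                        target, cand, core, allow_self_pairs=cfg.allow_self_pairs
                    )
                    tab.insert(0, "target", t)
                    tab["pool_mode"] = mode
                    tables.append(tab)
        pd.concat(tables, ignore_index=True).to_csv(out / "parentage.csv", index=False)
        # genome-specific contribution report
        contrib = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in poly_taxa:
                gc = parentage.genome_specific_contribution(
                    parentage.majority_genotype(gs, t), gs.panel
                )
                contrib[t] = {"counts": gc.counts, "ratio": gc.ratio,
                              "missing": gc.missing}
        (out / "genome_contributions.json").write_text(json.dumps(contrib, indent=1))
    except Exception as e:  # noqa: BLE001
        fail("parentage", e)

    # -- stage: ploidy -----------------------------------------------------
    stage("ploidy")
    if fcm_records:
        try:
            for r in fcm_records:
                r.relative_2c = ploidy.relative_2c(
                    r.sample_peak, r.standard_peak, r.standard_2c
                )
            if cfg.diploid_ref_taxon:
                ref = float(
                    np.mean(
                        [
                            r.relative_2c
                            for r in fcm_records
                            if r.taxon == cfg.diploid_ref_taxon
                        ]
                    )
                )
            else:
                dip = {
                    g.sample_id for g in gs.genotypes if g.ploidy == 2
                }
                vals = [r.relative_2c for r in fcm_records if r.sample_id in dip]
                ref = float(np.mean(vals)) if vals else float(
                    np.median([r.relative_2c for r in fcm_records])
                )
            ploidy.classify_records(
                fcm_records, ref, cfg.base_x, tolerance=cfg.ploidy_tolerance
            )
            ploidy.cytotype_table(fcm_records).to_csv(
                out / "cytotypes.csv", index=False
            )
            manifest["diploid_ref_2c"] = ref
        except Exception as e:  # noqa: BLE001
            fail("ploidy", e)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _plot_histogram(hist: clonal.DistanceHistogram, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
    ax.bar(centers, hist.counts, width=np.diff(hist.bin_edges), color="0.5")
    if hist.detected_threshold is not None:
        ax.axvline(hist.detected_threshold, ls="--", color="k")
    ax.set_xlabel("pairwise genetic distance")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
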