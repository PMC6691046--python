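"""End-to-end pipeline orchestration: simulate -> merge -> analyze.

Each stage reads and writes plain files under an output directory, so the
stages can be run separately (or from the command line, see
:mod:`cytofuse.cli`) and every run is reproducible from its manifest, which
records the configuration, the seed and the package version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SpecError
from .profiles import read_profile, write_profile, PanelSet
from .synthetic import make_hiv_cohort_preset, generate_cohort
from .merge import BackboneSpec, merge_panelset, merge_report
from .cluster import (
    ClusteringSpec,
    compute_cluster_stats,
    density_dependent_downsample,
    estimate_local_density,
    fit_clusters,
    pre_downsample,
    upsample_assign,
)
from .phenotype import (
    annotate_populations,
    build_heatmap,
    compute_marker_ranges,
    order_heatmap,
)
from .stats import AbundanceTable, classify_etc

__all__ = ["PipelineConfig", "run_simulate", "run_merge", "run_analyze", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Defaults follow the conventional full-scale analysis: arcsinh cofactor 5,
    backbone distance threshold 3, 5% density-dependent downsampling after a
    67,000-event random pre-downsample, k = 500 clusters, 5th/95th percentile
    ranges cut into five categories, a 50-cell minimum per assignable
    cluster, and a four-fold enrichment threshold.  ``n_events`` scales the
    synthetic cohort; the other knobs are the analysis parameters.
    """

    outdir: str = "cytofuse_out"
    seed: int = 0
    format: str = "tsv"
    # synthetic cohort
    n_events: int = 5000
    backbone_noise_sd: float = 0.05
    # transform / merge
    cofactor: float = 5.0
    threshold: float = 3.0
    # clustering
    k: int = 500
    downsample_fraction: float = 0.05
    pre_downsample_n: int | None = 67_000
    outlier_density_percentile: float = 1.0
    target_density_percentile: float = 5.0
    # phenotyping
    low_percentile: float = 5.0
    high_percentile: float = 95.0
    n_categories: int = 5
    min_cells: int = 50
    # differential
    fc_threshold: float = 4.0
    pseudocount: float = 1.0
    max_permutations: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig, extra: dict | None = None):
    manifest = {
        "stage": stage,
        "cytofuse_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        **(extra or {}),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the preset cohort and write per-individual, per-panel profiles.

    Also writes a ground-truth table (event id -> population) per individual,
    for scoring only.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = make_hiv_cohort_preset(seed=config.seed, n_events=config.n_events)
    spec = dataclasses.replace(spec, backbone_noise_sd=config.backbone_noise_sd)
    cohort = generate_cohort(spec)
    design = []
    for individual_id, (_, panelset, truth) in cohort.items():
        for panel_id, profile in panelset.profiles.items():
            safe = panel_id.replace("#", "")
            write_profile(profile, outdir / f"{individual_id}_{safe}.{config.format}", config.format)
        pd.DataFrame(
            {"event_id": np.arange(len(truth.populations)), "population": truth.populations}
        ).to_csv(outdir / f"{individual_id}_truth.tsv", sep="\t", index=False)
        design.append({"individual": individual_id, "condition": spec.condition_of(individual_id)})
    pd.DataFrame(design).to_csv(outdir / "design.tsv", sep="\t", index=False)
    pd.Series(spec.panels[0].backbone).to_csv(
        outdir / "backbone.tsv", sep="\t", index=False, header=["marker"]
    )
    _write_manifest(outdir, "simulate", config, {"individuals": [d["individual"] for d in design]})
    return outdir


def _load_design(outdir: Path) -> pd.DataFrame:
    design_path = outdir / "design.tsv"
    if not design_path.exists():
        raise SpecError(f"no design.tsv in {outdir}; run simulate first")
    return pd.read_csv(design_path, sep="\t")


def run_merge(config: PipelineConfig) -> pd.DataFrame:
    """Merge every individual's panels; write merged profiles and the report."""
    outdir = Path(config.outdir)
    design = _load_design(outdir)
    backbone = tuple(pd.read_csv(outdir / "backbone.tsv", sep="\t")["marker"])
    spec = BackboneSpec(markers=backbone, threshold=config.threshold)
    reports = []
    for individual in design["individual"]:
        profiles = {}
        for panel_id in ("#A", "#B", "#C"):
            safe = panel_id.replace("#", "")
            path = outdir / f"{individual}_{safe}.{config.format}"
            prof = read_profile(path, config.format, sample_id=individual, panel_id=panel_id)
            prof.transformed = True  # simulated profiles are stored in arcsinh units
            profiles[panel_id] = prof
        panelset = PanelSet(sample_id=individual, profiles=profiles, backbone=backbone)
        result = merge_panelset(panelset, spec=spec)
        write_profile(result.merged, outdir / f"{individual}_merged.{config.format}", config.format)
        reports.append(merge_report(result, sample_id=individual))
    report = pd.concat(reports, ignore_index=True)
    report.to_csv(outdir / "merge_report.tsv", sep="\t", index=False)
    _write_manifest(outdir, "merge", config)
    return report


def run_analyze(config: PipelineConfig) -> dict:
    """Cluster the merged profiles and write all downstream artifacts.

    Emits cluster assignments, centroids, the categorical heatmap (CSV with
    NA for unassigned clusters), dendrogram orders, population labels,
    enrichment-trend labels and the per-individual abundance table.
    """
    outdir = Path(config.outdir)
    design = _load_design(outdir)
    backbone = tuple(pd.read_csv(outdir / "backbone.tsv", sep="\t")["marker"])
    conditions = dict(zip(design["individual"], design["condition"]))

    merged = {}
    for individual in design["individual"]:
        prof = read_profile(
            outdir / f"{individual}_merged.{config.format}", config.format,
            sample_id=individual, panel_id="merged",
        )
        prof.transformed = True
        merged[individual] = prof
    markers = tuple(next(iter(merged.values())).markers)
    cspec = ClusteringSpec(
        clustering_markers=markers,
        k=config.k,
        downsample_fraction=config.downsample_fraction,
        pre_downsample_n=config.pre_downsample_n,
        outlier_density_percentile=config.outlier_density_percentile,
        target_density_percentile=config.target_density_percentile,
        seed=config.seed,
    )

    downsampled = []
    for i, (individual, profile) in enumerate(merged.items()):
        sub = profile
        if cspec.pre_downsample_n is not None and profile.n_events > cspec.pre_downsample_n:
            sub = pre_downsample(profile, cspec.pre_downsample_n, seed=config.seed * 7919 + i)
        x = sub.values(markers)
        dens = estimate_local_density(x, seed=config.seed * 104_729 + i)
        kept = density_dependent_downsample(x, dens, cspec, seed=config.seed * 1_299_709 + i)
        downsampled.append(x[kept])
    pooled = np.vstack(downsampled)

    model = fit_clusters(pooled, cspec)
    assignments = upsample_assign(model, merged)
    stats = compute_cluster_stats(assignments, merged, markers)
    ranges = compute_marker_ranges(
        merged.values(), markers, config.low_percentile, config.high_percentile
    )
    heatmap = build_heatmap(stats, ranges, min_cells=config.min_cells, n_categories=config.n_categories)
    order_heatmap(heatmap, backbone)
    populations = annotate_populations(heatmap)

    table = AbundanceTable(counts=stats.counts, conditions=conditions)
    etc = classify_etc(
        table, fc_threshold=config.fc_threshold,
        pseudocount=config.pseudocount, min_cells=config.min_cells,
    )

    model.centroids.to_csv(outdir / "centroids.tsv", sep="\t")
    rows = []
    for individual, assign in assignments.items():
        rows.append(pd.DataFrame({"individual": individual,
                                  "event_index": np.arange(len(assign)),
                                  "cluster": assign}))
    pd.concat(rows, ignore_index=True).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    heatmap.categories.to_csv(outdir / "heatmap.csv", na_rep="NA")
    pd.DataFrame({
        "kind": (["cluster"] * len(heatmap.row_order)
                 + ["backbone"] * len(heatmap.backbone_order)
                 + ["specific"] * len(heatmap.specific_order)),
        "item": [str(v) for v in heatmap.row_order + heatmap.backbone_order + heatmap.specific_order],
    }).to_csv(outdir / "heatmap_orders.tsv", sep="\t", index=False)
    populations.to_csv(outdir / "populations.tsv", sep="\t", header=True)
    etc.to_csv(outdir / "etc_labels.tsv", sep="\t")
    stats.counts.to_csv(outdir / "abundance.tsv", sep="\t")
    _write_manifest(outdir, "analyze", config, {"n_pooled_downsampled": int(pooled.shape[0])})
    return {
        "model": model,
        "assignments": assignments,
        "stats": stats,
        "heatmap": heatmap,
        "populations": populations,
        "etc": etc,
    }


def run_all(config: PipelineConfig) -> dict:
    """simulate + merge + analyze in one call."""
    run_simulate(config)
    run_merge(config)
    return run_analyze(config)
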