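import dataclasses

import numpy as np
import pytest

import cytofuse as cf
from cytofuse.cluster import (
    ClusteringSpec,
    compute_cluster_stats,
    density_dependent_downsample,
    estimate_local_density,
    fit_clusters,
    upsample_assign,
)
from cytofuse.phenotype import (
    annotate_populations,
    build_heatmap,
    compute_marker_ranges,
    order_heatmap,
)
from cytofuse.stats import AbundanceTable, classify_etc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_profile():
    return cf.CytometricProfile(
        events=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        markers=["m1", "m2"],
        sample_id="s1",
        panel_id="p1",
    )


@pytest.fixture(scope="session")
def preset_spec():
    """Desk-scale instance of the two-condition cohort preset."""
    return cf.make_hiv_cohort_preset(seed=11, n_events=2000)


@pytest.fixture(scope="session")
def preset_cohort(preset_spec):
    return cf.generate_cohort(preset_spec)


@pytest.fixture(scope="session")
def preset_analysis(preset_spec, preset_cohort):
    """Full in-memory pipeline run on the preset cohort (shared, read-only).

    Merges every individual, clusters the pooled density-downsampled cells,
    upsamples, categorises and classifies enrichment trends.
    """
    merged, truths = {}, {}
    for individual, (full, panelset, truth) in preset_cohort.items():
        result = cf.merge_panelset(panelset)
        merged[individual] = result.merged
        truths[individual] = truth
    markers = tuple(next(iter(merged.values())).markers)
    cspec = ClusteringSpec(
        clustering_markers=markers, k=20, downsample_fraction=0.10,
        pre_downsample_n=None, seed=7,
    )
    blocks = []
    for i, profile in enumerate(merged.values()):
        x = profile.values(markers)
        dens = estimate_local_density(x, seed=100 + i)
        kept = density_dependent_downsample(x, dens, cspec, seed=200 + i)
        blocks.append(x[kept])
    pooled = np.vstack(blocks)
    model = fit_clusters(pooled, cspec)
    assignments = upsample_assign(model, merged)
    stats = compute_cluster_stats(assignments, merged, markers)
    ranges = compute_marker_ranges(merged.values(), markers)
    heatmap = build_heatmap(stats, ranges, min_cells=50)
    order_heatmap(heatmap, cf.BACKBONE_MARKERS)
    populations = annotate_populations(heatmap)
    conditions = {i: c for i, c in preset_spec.individuals}
    table = AbundanceTable(counts=stats.counts, conditions=conditions)
    etc = classify_etc(table)
    return {
        "spec": preset_spec,
        "merged": merged,
        "truths": truths,
        "model": model,
        "assignments": assignments,
        "stats": stats,
        "heatmap": heatmap,
        "populations": populations,
        "etc": etc,
        "conditions": conditions,
    }
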