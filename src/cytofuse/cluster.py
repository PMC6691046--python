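"""Density-dependent downsampling, clustering and full upsampling.

This stage mirrors the user-facing behaviour of density-normalised
clustering tools for cytometry: a random pre-downsampling caps every sample
at a common size; local density is estimated per cell; dense regions are
thinned much harder than sparse ones so that rare populations survive into
the clustering set; the pooled downsampled cells of all individuals are cut
into ``k`` clusters by Ward agglomeration; finally *every* original cell is
assigned to its nearest cluster centroid (full upsampling).  The internals
(density kernel, linkage flavour) are this package's own documented choices;
the user-facing parameters -- downsampling fraction, pre-downsample size,
cluster count -- are the conventional ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .errors import SpecError
from .profiles import CytometricProfile

__all__ = [
    "ClusteringSpec",
    "ClusterModel",
    "ClusterStats",
    "pre_downsample",
    "estimate_local_density",
    "density_dependent_downsample",
    "fit_clusters",
    "upsample_assign",
    "compute_cluster_stats",
    "msi",
]


@dataclass(frozen=True)
class ClusteringSpec:
    """Parameters of the downsample / cluster / upsample stage.

    ``downsample_fraction`` is the expected kept fraction after
    density-dependent downsampling (0.05 by convention), ``pre_downsample_n``
    the per-sample random cap (often the size of the smallest sample), ``k``
    the number of clusters.  The density radius is derived from the data; the
    outlier and target density percentiles control which cells count as noise
    and what density the thinning equalises towards.
    """

    clustering_markers: tuple[str, ...]
    k: int = 500
    downsample_fraction: float = 0.05
    pre_downsample_n: int | None = 67_000
    outlier_density_percentile: float = 1.0
    target_density_percentile: float = 5.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "clustering_markers", tuple(self.clustering_markers))
        if not self.clustering_markers:
            raise SpecError("clustering_markers must be nonempty")
        if self.k < 1:
            raise SpecError("k must be >= 1")
        if not 0 < self.downsample_fraction <= 1:
            raise SpecError("downsample_fraction must be in (0, 1]")
        if not 0 <= self.outlier_density_percentile < 100:
            raise SpecError("outlier_density_percentile must be in [0, 100)")
        if not 0 < self.target_density_percentile <= 100:
            raise SpecError("target_density_percentile must be in (0, 100]")


@dataclass
class ClusterModel:
    """A fitted partition: per-cluster medians on the clustering markers."""

    centroids: pd.DataFrame  # index = cluster ids 1..k, columns = clustering markers
    clustering_markers: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.centroids)


@dataclass
class ClusterStats:
    """Per-cluster summaries after full upsampling.

    ``counts``: cluster x individual cell counts.
    ``medians``: (cluster, individual) x marker per-individual medians,
    defined only where the individual has cells in the cluster.
    ``mean_of_medians``: cluster x marker, the unweighted mean of the
    individual medians -- the expression summary used for categorisation.
    ``total``: whole-dataset cell count per cluster.
    """

    counts: pd.DataFrame
    medians: pd.DataFrame
    mean_of_medians: pd.DataFrame
    total: pd.Series


def pre_downsample(profile: CytometricProfile, n: int, seed: int = 0) -> CytometricProfile:
    """Uniform random subset of ``n`` events without replacement (seeded).

    If the profile holds fewer than ``n`` events, all of them are taken (in
    random order) with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    if n > profile.n_events:
        warnings.warn(
            f"requested {n} events but profile {profile.sample_id!r} has "
            f"{profile.n_events}; taking all", stacklevel=2,
        )
        n = profile.n_events
    idx = rng.permutation(profile.n_events)[:n]
    return _take(profile, idx)


def _take(profile: CytometricProfile, idx: np.ndarray) -> CytometricProfile:
    return CytometricProfile(
        events=profile.events[idx],
        markers=list(profile.markers),
        sample_id=profile.sample_id,
        panel_id=profile.panel_id,
        transformed=profile.transformed,
        event_ids=None if profile.event_ids is None else profile.event_ids[idx],
    )


def estimate_local_density(
    matrix: np.ndarray, seed: int = 0, radius_subsample: int = 2000, radius_factor: float = 5.0
) -> np.ndarray:
    """Local density of every event: neighbours within a data-derived radius.

    The radius is ``radius_factor`` times the median nearest-neighbour
    distance of a seeded ``radius_subsample``-event subsample (all events if
    fewer).  The count includes the event itself, so identical events all get
    density ``n``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise SpecError("density is undefined for fewer than two events")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    sub = matrix if n <= radius_subsample else matrix[rng.permutation(n)[:radius_subsample]]
    sub_tree = cKDTree(sub)
    nn_dist = sub_tree.query(sub, k=2)[0][:, 1]
    r = radius_factor * float(np.median(nn_dist))
    tree = cKDTree(matrix)
    return tree.query_ball_point(matrix, r, return_length=True).astype(float)


def density_dependent_downsample(
    matrix: np.ndarray, densities: np.ndarray, spec: ClusteringSpec, seed: int = 0
) -> np.ndarray:
    """Indices of the events kept by density-dependent downsampling.

    Cells below the outlier density percentile are discarded as noise.  Cells
    below the target density TD (the ``target_density_percentile`` of the
    remaining densities) are kept outright; denser cells are kept with
    probability ``TD / density``, which equalises the kept density landscape
    and so protects rare populations.  If the expected kept fraction still
    exceeds ``downsample_fraction``, a final uniform thinning brings the
    expected kept count down to ``fraction * n``.
    """
    matrix = np.asarray(matrix)
    densities = np.asarray(densities, dtype=float)
    if densities.shape[0] != matrix.shape[0]:
        raise SpecError("densities are not aligned with the matrix")
    n = matrix.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))

    outlier_cut = np.percentile(densities, spec.outlier_density_percentile)
    survivors = np.flatnonzero(densities >= outlier_cut)
    if survivors.size == 0:
        return survivors
    td = np.percentile(densities[survivors], spec.target_density_percentile)
    keep_p = np.minimum(1.0, td / np.maximum(densities[survivors], 1e-300))
    expected = keep_p.sum()
    budget = spec.downsample_fraction * n
    if expected > budget:
        keep_p *= budget / expected
    kept = survivors[rng.random(survivors.size) < keep_p]
    return kept


def fit_clusters(matrix: np.ndarray, spec: ClusteringSpec) -> ClusterModel:
    """Cut a Ward dendrogram of the pooled downsampled events at ``k`` clusters.

    Agglomeration uses Euclidean distance on the clustering markers; cluster
    centroids are the per-cluster medians.  Cluster ids are 1..k.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(spec.clustering_markers):
        raise SpecError("matrix columns must match clustering_markers")
    if matrix.shape[0] < spec.k:
        raise SpecError(
            f"cannot form {spec.k} clusters from {matrix.shape[0]} events"
        )
    labels = fcluster(linkage(matrix, method="ward"), t=spec.k, criterion="maxclust")
    centroids = (
        pd.DataFrame(matrix, columns=list(spec.clustering_markers))
        .groupby(labels)
        .median()
        .sort_index()
    )
    centroids.index.name = "cluster"
    return ClusterModel(centroids=centroids, clustering_markers=spec.clustering_markers)


def upsample_assign(model: ClusterModel, profiles: dict) -> dict:
    """Assign every cell of every individual to its nearest cluster centroid.

    Euclidean distance on the clustering markers; exact distance ties go to
    the lowest cluster id.  Returns ``{individual: int array of cluster ids}``.
    """
    cent = model.centroids.to_numpy()
    ids = model.centroids.index.to_numpy()
    out = {}
    for individual, profile in profiles.items():
        x = profile.values(model.clustering_markers)
        assign = np.empty(x.shape[0], dtype=ids.dtype)
        for start in range(0, x.shape[0], 8192):
            chunk = x[start : start + 8192]
            d2 = ((chunk[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
            assign[start : start + 8192] = ids[np.argmin(d2, axis=1)]
        out[individual] = assign
    return out


def msi(values: np.ndarray) -> float:
    """Mean signal intensity of a cell set (plain mean expression)."""
    return float(np.mean(values))


def compute_cluster_stats(assignments: dict, profiles: dict, markers) -> ClusterStats:
    """Counts and expression summaries per cluster.

    Per cluster and individual: cell count and per-marker median.  Per
    cluster and marker: the unweighted mean of the individual medians over
    individuals that have at least one cell there (so a large individual does
    not dominate the summary).
    """
    markers = list(markers)
    frames = []
    for individual, assign in assignments.items():
        profile = profiles[individual]
        if len(assign) != profile.n_events:
            raise SpecError(f"assignments for {individual} do not cover all events")
        df = pd.DataFrame(profile.values(markers), columns=markers)
        df["cluster"] = np.asarray(assign)
        df["individual"] = individual
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)

    counts = (
        pooled.groupby(["cluster", "individual"]).size().unstack(fill_value=0).sort_index()
    )
    medians = pooled.groupby(["cluster", "individual"])[markers].median()
    mean_of_medians = medians.groupby(level="cluster").mean()
    total = counts.sum(axis=1)
    total.name = "total"
    return ClusterStats(
        counts=counts, medians=medians, mean_of_medians=mean_of_medians, total=total
    )
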