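"""Categorical cluster-by-marker heatmaps and rule-based population labels.

Marker expression is made comparable across markers by mapping each marker's
5th-95th percentile range (over the pooled cells of all individuals) onto
five uniform categories -- negative, low, medium, high, bright.  Each cluster
is then summarised by the category of its mean-of-individual-medians per
marker.  Clusters carrying fewer than ``min_cells`` cells over the whole
dataset cannot support a meaningful expression summary and are flagged
unassigned.  Rows and columns are ordered by hierarchical clustering
(Euclidean distance, complete linkage) of the categorical values, with the
backbone and panel-specific marker blocks ordered separately, and clusters
are given population labels by a small editable rule table over categories of
lineage markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import SpecError
from .cluster import ClusterStats

__all__ = [
    "MarkerRange",
    "CategoricalHeatmap",
    "AnnotationRule",
    "CATEGORY_LABELS",
    "DEFAULT_ANNOTATION_RULES",
    "compute_marker_ranges",
    "categorize",
    "build_heatmap",
    "order_heatmap",
    "annotate_populations",
]

CATEGORY_LABELS = {1: "negative", 2: "low", 3: "medium", 4: "high", 5: "bright"}


@dataclass(frozen=True)
class MarkerRange:
    """Empirical expression range of one marker (5th / 95th percentiles)."""

    marker: str
    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise SpecError(f"{self.marker}: low > high")


@dataclass(frozen=True)
class AnnotationRule:
    """A population label with its category predicates.

    ``predicates`` is a sequence of ``(marker, comparator, category)`` with
    comparator one of ``<=, <, >=, >, ==``.  Rules are evaluated in priority
    order; the first rule whose predicates all hold labels the cluster.
    """

    population: str
    predicates: tuple

    def __post_init__(self):
        object.__setattr__(self, "predicates", tuple(tuple(p) for p in self.predicates))
        for _, op, _ in self.predicates:
            if op not in ("<=", "<", ">=", ">", "=="):
                raise SpecError(f"unknown comparator {op!r}")


#: Declared heuristics for the major leukocyte lineages.  Order matters:
#: first match wins.  Category 4 = high, 5 = bright.
DEFAULT_ANNOTATION_RULES = (
    AnnotationRule("PMN", ((("CD66"), ">=", 4),)),
    AnnotationRule("T cell", ((("CD3"), ">=", 4), (("CD66"), "<=", 3), (("CD19"), "<=", 3))),
    AnnotationRule("B cell", ((("CD19"), ">=", 4), (("CD3"), "<=", 3))),
    AnnotationRule("pDC", ((("CD123"), ">=", 4), (("HLADR"), ">=", 4), (("CD11c"), "<=", 3))),
    AnnotationRule("Basophil", ((("CD123"), ">=", 4), (("HLADR"), "<=", 3))),
    AnnotationRule("Monocyte", ((("CD14"), ">=", 4), (("HLADR"), ">=", 4))),
    AnnotationRule("mDC", ((("CD11c"), ">=", 4), (("HLADR"), ">=", 4), (("CD14"), "<=", 3))),
    AnnotationRule("NK cell", ((("GranzymeB"), ">=", 4), (("CD3"), "<=", 3), (("CD66"), "<=", 3))),
)


@dataclass
class CategoricalHeatmap:
    """Cluster x marker categories plus orderings and population labels.

    ``categories`` holds integers 1..5 (nullable Int64; NA on unassigned
    rows).  ``unassigned`` flags clusters whose whole-dataset cell count is
    below the minimum.  The three orders are filled by
    :func:`order_heatmap`; ``populations`` by :func:`annotate_populations`.
    """

    categories: pd.DataFrame
    unassigned: pd.Series
    min_cells: int
    row_order: list = field(default_factory=list)
    backbone_order: list = field(default_factory=list)
    specific_order: list = field(default_factory=list)
    populations: pd.Series | None = None

    @property
    def markers(self) -> list[str]:
        return list(self.categories.columns)


def compute_marker_ranges(profiles, markers, low_pct: float = 5.0, high_pct: float = 95.0) -> list[MarkerRange]:
    """Percentile expression range per marker over the pooled cells.

    ``profiles`` is an iterable of :class:`CytometricProfile`; cells of all
    individuals are pooled before taking the percentiles
    (linear-interpolation convention), so categories are comparable across
    clusters and individuals.
    """
    markers = list(markers)
    pooled = np.vstack([p.values(markers) for p in profiles])
    if pooled.shape[0] < 1:
        raise SpecError("need at least one cell to compute ranges")
    lows = np.percentile(pooled, low_pct, axis=0)
    highs = np.percentile(pooled, high_pct, axis=0)
    return [MarkerRange(m, float(lo), float(hi)) for m, lo, hi in zip(markers, lows, highs)]


def categorize(value, range_: MarkerRange, n_categories: int = 5):
    """Map expression values onto uniform categories over the marker range.

    The range is divided into ``n_categories`` bins of equal width; values at
    or below the low bound clamp to category 1, values at or above the high
    bound clamp to the top category; interior bin edges belong to the upper
    bin.  Works elementwise on arrays.  A degenerate range (low == high)
    yields category 1 at or below the bound and the top category above it.
    """
    v = np.asarray(value, dtype=float)
    lo, hi = range_.low, range_.high
    if hi == lo:
        cat = np.where(v <= lo, 1, n_categories)
    else:
        width = (hi - lo) / n_categories
        cat = 1 + np.floor((v - lo) / width)
        cat = np.clip(cat, 1, n_categories)
        cat = np.where(v >= hi, n_categories, cat)
        cat = np.where(v <= lo, 1, cat)
    cat = cat.astype(int)
    return int(cat) if np.isscalar(value) or cat.ndim == 0 else cat


def build_heatmap(stats: ClusterStats, ranges, min_cells: int = 50, n_categories: int = 5) -> CategoricalHeatmap:
    """Categorise every cluster's mean-of-individual-medians per marker.

    Clusters with fewer than ``min_cells`` cells over the whole dataset are
    set to NA across all markers and flagged unassigned.
    """
    by_marker = {r.marker: r for r in ranges}
    missing = [m for m in stats.mean_of_medians.columns if m not in by_marker]
    if missing:
        raise SpecError(f"no range for markers: {missing}")
    cats = pd.DataFrame(index=stats.mean_of_medians.index, columns=stats.mean_of_medians.columns, dtype=object)
    for m in stats.mean_of_medians.columns:
        cats[m] = categorize(stats.mean_of_medians[m].to_numpy(), by_marker[m], n_categories)
    cats = cats.astype("Int64")
    unassigned = stats.total.reindex(cats.index).fillna(0) < min_cells
    cats.loc[unassigned, :] = pd.NA
    return CategoricalHeatmap(categories=cats, unassigned=unassigned, min_cells=min_cells)


def _complete_leaf_order(matrix: np.ndarray) -> list[int]:
    if matrix.shape[0] < 2:
        return list(range(matrix.shape[0]))
    return list(leaves_list(linkage(matrix, method="complete", metric="euclidean")))


def order_heatmap(heatmap: CategoricalHeatmap, backbone_markers) -> tuple[list, list, list]:
    """Dendrogram leaf orders for rows and the two marker blocks.

    Three complete-linkage hierarchical clusterings on the categorical
    matrix: one over assigned cluster rows (unassigned rows are appended
    last, in index order), one over backbone-marker columns and one over
    panel-specific columns.  With fewer than two assigned clusters, row order
    is the identity.  The orders are stored on the heatmap and returned as
    (row_order, backbone_order, specific_order) of labels.
    """
    backbone = [m for m in heatmap.markers if m in set(backbone_markers)]
    specific = [m for m in heatmap.markers if m not in set(backbone_markers)]
    assigned = heatmap.categories.loc[~heatmap.unassigned]
    values = assigned.to_numpy(dtype=float)

    if len(assigned) < 2:
        row_order = list(heatmap.categories.index)
    else:
        leaf = _complete_leaf_order(values)
        row_order = [assigned.index[i] for i in leaf]
        row_order += list(heatmap.categories.index[heatmap.unassigned])

    def _col_order(cols):
        if len(cols) < 2 or len(assigned) == 0:
            return list(cols)
        leaf = _complete_leaf_order(assigned[cols].to_numpy(dtype=float).T)
        return [cols[i] for i in leaf]

    backbone_order = _col_order(backbone)
    specific_order = _col_order(specific)
    heatmap.row_order = row_order
    heatmap.backbone_order = backbone_order
    heatmap.specific_order = specific_order
    return row_order, backbone_order, specific_order


def annotate_populations(heatmap: CategoricalHeatmap, rules=DEFAULT_ANNOTATION_RULES) -> pd.Series:
    """Label clusters with the first rule whose predicates all hold.

    Unassigned clusters stay ``"unassigned"``; clusters matching no rule get
    ``"unannotated"``.  The labels are stored on the heatmap and returned.
    """
    known = set(heatmap.markers)
    for rule in rules:
        for marker, _, _ in rule.predicates:
            if marker not in known:
                raise SpecError(
                    f"rule {rule.population!r} references missing marker {marker!r}"
                )
    ops = {
        "<=": lambda a, b: a <= b,
        "<": lambda a, b: a < b,
        ">=": lambda a, b: a >= b,
        ">": lambda a, b: a > b,
        "==": lambda a, b: a == b,
    }
    labels = {}
    for cluster in heatmap.categories.index:
        if heatmap.unassigned.loc[cluster]:
            labels[cluster] = "unassigned"
            continue
        row = heatmap.categories.loc[cluster]
        label = "unannotated"
        for rule in rules:
            if all(ops[op](int(row[m]), cat) for m, op, cat in rule.predicates):
                label = rule.population
                break
        labels[cluster] = label
    series = pd.Series(labels, name="population")
    series.index.name = heatmap.categories.index.name
    heatmap.populations = series
    return series
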