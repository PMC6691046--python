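"""Merging of multi-tube cytometric profiles on a shared marker backbone.

Two panels stain different aliquots of the same sample, so the same cell
physically appears (at most) once per panel but never as linked rows.  The
merge recovers the linkage from phenotype alone: cells are paired across
profiles when they are *acceptable* (backbone Euclidean distance at or below
a threshold) and *non-ambiguous* (mutual) nearest neighbours.  Matched pairs
become one output cell whose backbone phenotype is the average of the two
contributors and whose panel-specific markers are copied verbatim; matching
repeats on the residual unmatched cells until a round adds no pair.  Cells
that never find a partner are excluded and accounted for.

All distances are computed on arcsinh-transformed intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FormatError, SpecError
from .profiles import CytometricProfile, PanelSet

__all__ = [
    "BackboneSpec",
    "MergeMatch",
    "MergeResult",
    "backbone_distance",
    "match_profiles",
    "merge_two",
    "merge_panelset",
    "merge_report",
    "merge_accounting",
]

# below this many pairwise distances, use a dense matrix so that exact
# distance ties break toward the lowest row index; above it, a k-d tree
_DENSE_LIMIT = 2_000_000


@dataclass(frozen=True)
class BackboneSpec:
    """Backbone marker list and the acceptability threshold for matching."""

    markers: tuple[str, ...]
    threshold: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(self.markers) < 1:
            raise SpecError("backbone must contain at least one marker")
        if not self.threshold > 0:
            raise SpecError(f"threshold must be > 0, got {self.threshold}")


@dataclass
class MergeMatch:
    """Outcome of matching two profiles: index pairs plus leftovers."""

    pairs: list  # (row in A, row in B, backbone distance)
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class MergeResult:
    """A merged profile with per-input accounting and provenance.

    ``n_excluded`` counts original input cells that do not contribute to any
    cell of the final profile: for a k-profile merge it equals
    ``sum(n_input) - k * n_merged``.
    """

    merged: CytometricProfile
    n_input: dict
    n_merged: int
    n_excluded: int
    provenance: list = field(default_factory=list)  # per merged cell: {panel_id: input row}

    def __post_init__(self):
        k = len(self.n_input)
        expected = sum(self.n_input.values()) - k * self.n_merged
        if self.n_excluded != expected:
            raise SpecError(
                f"accounting violated: excluded {self.n_excluded} != "
                f"sum(inputs) - {k} * merged = {expected}"
            )
        if self.n_input and self.n_merged > min(self.n_input.values()):
            raise SpecError("merged count exceeds the smallest input")


def merge_accounting(n_input: dict, n_merged: int) -> int:
    """Excluded-cell count for a k-profile merge from the cell counts alone."""
    return int(sum(n_input.values()) - len(n_input) * n_merged)


def backbone_distance(a, b, spec: BackboneSpec) -> float:
    """Euclidean distance between two event rows over the backbone markers.

    Rows may be mappings (dict / pandas Series) from marker name to value.
    """
    try:
        va = np.asarray([a[m] for m in spec.markers], dtype=float)
        vb = np.asarray([b[m] for m in spec.markers], dtype=float)
    except KeyError as exc:
        from .errors import MarkerLookupError

        raise MarkerLookupError(exc.args[0]) from None
    return float(np.sqrt(np.sum((va - vb) ** 2)))


def _nearest(queries: np.ndarray, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest neighbour of each query among points.

    Returns (index, distance).  Ties break toward the lowest point index on
    the dense path; the k-d-tree path is deterministic for a fixed input.
    """
    if queries.shape[0] * points.shape[0] <= _DENSE_LIMIT:
        d2 = np.sum((queries[:, None, :] - points[None, :, :]) ** 2, axis=2)
        idx = np.argmin(d2, axis=1)
        return idx, np.sqrt(d2[np.arange(len(queries)), idx])
    tree = cKDTree(points)
    dist, idx = tree.query(queries, k=1)
    return idx, dist


def match_profiles(a: CytometricProfile, b: CytometricProfile, spec: BackboneSpec) -> MergeMatch:
    """Pair cells of two profiles by iterated acceptable mutual nearest neighbours.

    Each round, among still-unmatched cells, ``(i, j)`` is matched when ``j``
    is ``i``'s nearest unmatched neighbour in B, ``i`` is ``j``'s nearest
    unmatched neighbour in A, and their backbone distance does not exceed the
    threshold.  Matched cells leave the pool and the search repeats on the
    remainder until a round produces no new pair.
    """
    if not (a.transformed and b.transformed):
        raise SpecError("profiles must be arcsinh-transformed before matching")
    xa = a.values(spec.markers)
    xb = b.values(spec.markers)
    active_a = np.arange(xa.shape[0])
    active_b = np.arange(xb.shape[0])
    pairs: list[tuple[int, int, float]] = []

    while active_a.size and active_b.size:
        nb_idx, nb_dist = _nearest(xa[active_a], xb[active_b])
        na_idx, _ = _nearest(xb[active_b], xa[active_a])
        # mutual = each is the other's nearest among the active pools
        mutual = na_idx[nb_idx] == np.arange(active_a.size)
        acceptable = nb_dist <= spec.threshold
        hit = mutual & acceptable
        if not hit.any():
            break
        ia = np.flatnonzero(hit)
        for pos in ia:
            pairs.append(
                (int(active_a[pos]), int(active_b[nb_idx[pos]]), float(nb_dist[pos]))
            )
        active_a = np.delete(active_a, ia)
        active_b = np.delete(active_b, nb_idx[ia])
    return MergeMatch(pairs=pairs, unmatched_a=active_a, unmatched_b=active_b)


def merge_two(a: CytometricProfile, b: CytometricProfile, match: MergeMatch,
              backbone: tuple[str, ...]) -> CytometricProfile:
    """Build the merged profile of two matched inputs.

    One output cell per pair.  Backbone columns are the arithmetic mean of
    the two contributors; panel-specific columns are copied from whichever
    input measured them.  Column order: backbone, then A-specific, then
    B-specific.
    """
    backbone = tuple(backbone)
    a_specific = [m for m in a.markers if m not in backbone]
    b_specific = [m for m in b.markers if m not in backbone]
    collision = set(a_specific) & set(b_specific)
    if collision:
        raise FormatError(
            f"non-backbone markers measured by both inputs: {sorted(collision)}"
        )
    ia = np.asarray([p[0] for p in match.pairs], dtype=np.intp)
    ib = np.asarray([p[1] for p in match.pairs], dtype=np.intp)
    bb = 0.5 * (a.values(backbone)[ia] + b.values(backbone)[ib])
    cols = [bb]
    if a_specific:
        cols.append(a.values(a_specific)[ia])
    if b_specific:
        cols.append(b.values(b_specific)[ib])
    events = np.hstack(cols) if ia.size else np.empty((0, len(backbone) + len(a_specific) + len(b_specific)))
    event_ids = a.event_ids[ia] if a.event_ids is not None and ia.size else (
        a.event_ids[:0] if a.event_ids is not None else None
    )
    return CytometricProfile(
        events=events,
        markers=list(backbone) + a_specific + b_specific,
        sample_id=a.sample_id,
        panel_id=f"{a.panel_id}+{b.panel_id}".lstrip("+"),
        transformed=True,
        event_ids=event_ids,
    )


def merge_panelset(panelset: PanelSet, order=None, spec: BackboneSpec | None = None) -> MergeResult:
    """Sequentially merge all panels of a sample into one wide profile.

    Panels are merged in the given order (default: panel-set order): the
    first two are merged, then the intermediate -- whose backbone is already
    the average of its contributors -- is merged with the next panel, and so
    on.  Provenance chains record, for every final cell, the contributing
    row of every input panel.
    """
    order = list(order) if order is not None else panelset.panel_ids
    unknown = [p for p in order if p not in panelset.profiles]
    if unknown:
        raise SpecError(f"order references unknown panels: {unknown}")
    if len(order) < 2:
        raise SpecError("need at least two panels to merge")
    if spec is None:
        spec = BackboneSpec(markers=panelset.backbone)

    current = panelset.profiles[order[0]]
    provenance = [{order[0]: i} for i in range(current.n_events)]
    for panel_id in order[1:]:
        nxt = panelset.profiles[panel_id]
        match = match_profiles(current, nxt, spec)
        current = merge_two(current, nxt, match, spec.markers)
        provenance = [
            {**provenance[i], panel_id: j} for (i, j, _) in match.pairs
        ]
    n_input = {p: panelset.profiles[p].n_events for p in order}
    n_merged = current.n_events
    return MergeResult(
        merged=current,
        n_input=n_input,
        n_merged=n_merged,
        n_excluded=merge_accounting(n_input, n_merged),
        provenance=provenance,
    )


def merge_report(result: MergeResult, sample_id: str | None = None) -> pd.DataFrame:
    """Tabulate a merge: one row per input profile plus one combined row.

    Columns: sample, profile, n_cells, n_merged, n_excluded (the latter two
    filled only on the combined row).  Serialisable as TSV.
    """
    sample = sample_id if sample_id is not None else result.merged.sample_id
    rows = [
        {"sample": sample, "profile": pid, "n_cells": n, "n_merged": pd.NA, "n_excluded": pd.NA}
        for pid, n in result.n_input.items()
    ]
    combined = "+".join(result.n_input)
    rows.append(
        {
            "sample": sample,
            "profile": combined,
            "n_cells": pd.NA,
            "n_merged": result.n_merged,
            "n_excluded": result.n_excluded,
        }
    )
    return pd.DataFrame(rows, columns=["sample", "profile", "n_cells", "n_merged", "n_excluded"])
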