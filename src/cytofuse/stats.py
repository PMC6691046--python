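"""Differential cluster abundance and permutation-based group comparison.

Two complementary readouts of condition differences:

* enrichment-trend classification -- a cluster whose (per-individual
  normalised) cell abundance differs between the two conditions by more than
  a fold-change threshold (4 by default) is an enrichment trend cluster,
  labelled by the direction of its enrichment;
* non-parametric permutation tests -- per-individual summary statistics
  (e.g. a population's mean marker intensity, MSI) are compared across
  conditions by relabelling individuals, exhaustively whenever the design is
  small enough, Monte-Carlo otherwise.

With 3-vs-3 individuals there are only C(6,3) = 20 relabelings, so the
smallest attainable two-sided p-value is 2/20 = 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import SpecError
from .cluster import msi

__all__ = [
    "AbundanceTable",
    "PermutationTestResult",
    "classify_etc",
    "permutation_test",
    "compare_population_msi",
]

CONDITIONS = ("HEA", "HIV")


@dataclass
class AbundanceTable:
    """Cluster x individual cell counts plus the condition of each individual.

    ``totals`` are the per-individual normalisation totals; by default the
    column sums of the count table.
    """

    counts: pd.DataFrame
    conditions: dict
    totals: pd.Series | None = None

    def __post_init__(self):
        unknown = set(self.conditions.values()) - set(CONDITIONS)
        if unknown:
            raise SpecError(f"unknown conditions: {sorted(unknown)}")
        missing = [i for i in self.counts.columns if i not in self.conditions]
        if missing:
            raise SpecError(f"individuals without a condition: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise SpecError("negative cell counts")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)
        if (self.totals <= 0).any():
            zero = list(self.totals.index[self.totals <= 0])
            raise SpecError(f"individuals with zero total cells: {zero}")

    def individuals(self, condition: str) -> list:
        return [i for i in self.counts.columns if self.conditions[i] == condition]


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed statistic and its permutation p-value."""

    observed: float
    p_value: float
    n_permutations: int
    exhaustive: bool

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise SpecError(f"p-value out of range: {self.p_value}")


def classify_etc(
    table: AbundanceTable,
    fc_threshold: float = 4.0,
    pseudocount: float = 1.0,
    min_cells: int = 50,
) -> pd.DataFrame:
    """Enrichment-trend classification of every cluster.

    Normalised abundance of a cluster in a condition is the sum over that
    condition's individuals of ``count / individual total``.  The fold change
    is ``(a_HIV + eps) / (a_HEA + eps)`` with ``eps`` the pseudocount scaled
    to proportions (one cell at the smallest individual total by default), so
    zero abundances stay finite.  Labels: ``enriched_HIV`` when the fold
    change exceeds the threshold, ``enriched_HEA`` when its inverse does,
    ``none`` otherwise, and ``unassigned`` for clusters carrying fewer than
    ``min_cells`` cells over the whole dataset.

    Returns a frame indexed by cluster with columns ``abundance_HEA``,
    ``abundance_HIV``, ``fold_change``, ``label``.
    """
    hea = table.individuals("HEA")
    hiv = table.individuals("HIV")
    if not hea or not hiv:
        raise SpecError("both conditions need at least one individual")
    proportions = table.counts / table.totals
    a_hea = proportions[hea].sum(axis=1)
    a_hiv = proportions[hiv].sum(axis=1)
    eps = pseudocount / float(table.totals.min())
    fc = (a_hiv + eps) / (a_hea + eps)
    label = pd.Series("none", index=table.counts.index, dtype=object)
    label[fc > fc_threshold] = "enriched_HIV"
    label[(1.0 / fc) > fc_threshold] = "enriched_HEA"
    label[table.counts.sum(axis=1) < min_cells] = "unassigned"
    return pd.DataFrame(
        {"abundance_HEA": a_hea, "abundance_HIV": a_hiv, "fold_change": fc, "label": label}
    )


def _abs_mean_diff(x: np.ndarray, y: np.ndarray) -> float:
    return abs(float(np.mean(x)) - float(np.mean(y)))


def permutation_test(
    x, y, statistic=None, max_permutations: int = 10_000, seed: int = 0
) -> PermutationTestResult:
    """Two-sample permutation test on per-individual values.

    The default statistic is the absolute difference of group means.  When
    the number of distinct relabelings ``C(n1+n2, n1)`` is at most
    ``max_permutations`` the null distribution is enumerated exhaustively and
    ``p = #(stat >= observed) / total``; otherwise ``max_permutations``
    Monte-Carlo relabelings are drawn (seeded) and the add-one convention
    ``p = (1 + #exceedances) / (1 + draws)`` keeps p strictly positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise SpecError("both groups must be nonempty")
    stat = statistic or _abs_mean_diff
    observed = float(stat(x, y))
    pooled = np.concatenate([x, y])
    n1, n = x.size, x.size + y.size
    tol = 1e-12 * max(1.0, abs(observed))

    n_total = math.comb(n, n1)
    if n_total <= max_permutations:
        if statistic is None:
            # default statistic: vectorise over the full enumeration
            combos = np.fromiter(
                (i for combo in combinations(range(n), n1) for i in combo),
                dtype=np.intp, count=n_total * n1,
            ).reshape(n_total, n1)
            sums = pooled[combos].sum(axis=1)
            stats = np.abs(sums / n1 - (pooled.sum() - sums) / (n - n1))
            exceed = int((stats >= observed - tol).sum())
        else:
            exceed = 0
            idx_all = frozenset(range(n))
            for combo in combinations(range(n), n1):
                gx = pooled[list(combo)]
                gy = pooled[list(idx_all - set(combo))]
                if stat(gx, gy) >= observed - tol:
                    exceed += 1
        return PermutationTestResult(
            observed=observed,
            p_value=exceed / n_total,
            n_permutations=n_total,
            exhaustive=True,
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    exceed = 0
    for _ in range(max_permutations):
        perm = rng.permutation(n)
        if stat(pooled[perm[:n1]], pooled[perm[n1:]]) >= observed - tol:
            exceed += 1
    return PermutationTestResult(
        observed=observed,
        p_value=(1 + exceed) / (1 + max_permutations),
        n_permutations=max_permutations,
        exhaustive=False,
    )


def compare_population_msi(
    profiles: dict,
    masks: dict,
    markers,
    conditions: dict,
    max_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation tests of a population's per-marker MSI across conditions.

    Each individual contributes one MSI per marker: the mean expression over
    the cells selected by its boolean ``mask``.  Individuals with an empty
    population are excluded with a warning.  Returns one row per marker with
    the group MSI means, the signed difference (HIV minus HEA), the two-sided
    permutation p-value and the enumeration details.
    """
    markers = list(markers)
    usable = []
    for individual, profile in profiles.items():
        mask = np.asarray(masks[individual], dtype=bool)
        if mask.sum() == 0:
            warnings.warn(
                f"individual {individual!r} has no cells in the population; excluded",
                stacklevel=2,
            )
            continue
        usable.append(individual)
    hea = [i for i in usable if conditions[i] == "HEA"]
    hiv = [i for i in usable if conditions[i] == "HIV"]
    if not hea or not hiv:
        raise SpecError("both conditions need at least one usable individual")

    rows = []
    for m_i, marker in enumerate(markers):
        per_ind = {
            i: msi(profiles[i].values([marker])[np.asarray(masks[i], dtype=bool)])
            for i in usable
        }
        x = np.asarray([per_ind[i] for i in hiv])
        y = np.asarray([per_ind[i] for i in hea])
        res = permutation_test(
            x, y, max_permutations=max_permutations, seed=seed * 1000 + m_i
        )
        rows.append(
            {
                "marker": marker,
                "msi_HEA": float(y.mean()),
                "msi_HIV": float(x.mean()),
                "difference": float(x.mean() - y.mean()),
                "direction": "up_in_HIV" if x.mean() > y.mean() else "up_in_HEA",
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
            }
        )
    return pd.DataFrame(rows).set_index("marker")
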