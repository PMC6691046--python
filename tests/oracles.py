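"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive (exhaustive scans, O(n^2) or worse) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def mutual_nn_pairs(xa: np.ndarray, xb: np.ndarray, threshold: float) -> set:
    """Exhaustive repeat-until-stable acceptable mutual-nearest-neighbour rule.

    Scans all pairwise distances each round; a pair is matched when each cell
    is the other's nearest remaining neighbour and their distance is within
    the threshold; matched cells leave the pool until a round adds nothing.
    """
    pairs: set[tuple[int, int]] = set()
    remaining_a = list(range(len(xa)))
    remaining_b = list(range(len(xb)))
    while remaining_a and remaining_b:
        found = []
        for a in remaining_a:
            d_ab = [float(np.linalg.norm(xa[a] - xb[b])) for b in remaining_b]
            b = remaining_b[int(np.argmin(d_ab))]
            d_ba = [float(np.linalg.norm(xb[b] - xa[a2])) for a2 in remaining_a]
            if remaining_a[int(np.argmin(d_ba))] == a and min(d_ab) <= threshold:
                found.append((a, b))
        if not found:
            break
        for a, b in found:
            remaining_a.remove(a)
            remaining_b.remove(b)
        pairs |= set(found)
    return pairs


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Sum-of-squares Euclidean distance, written out longhand."""
    total = 0.0
    for x, y in zip(a, b):
        total += (float(x) - float(y)) ** 2
    return total ** 0.5


def density_counts(matrix: np.ndarray, radius: float) -> np.ndarray:
    """Events within ``radius`` of each event (self included), pairwise scan."""
    n = len(matrix)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if euclidean(matrix[i], matrix[j]) <= radius:
                out[i] += 1
    return out


def median_nn_distance(matrix: np.ndarray) -> float:
    """Median distance to the nearest other event, pairwise scan."""
    n = len(matrix)
    nn = []
    for i in range(n):
        dists = [euclidean(matrix[i], matrix[j]) for j in range(n) if j != i]
        nn.append(min(dists))
    return float(np.median(nn))


def complete_linkage_heights(matrix: np.ndarray) -> list:
    """Merge heights of naive complete-linkage agglomeration."""
    clusters = [[i] for i in range(len(matrix))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    euclidean(matrix[a], matrix[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def enumerate_mean_diff_pvalue(x, y) -> float:
    """Exhaustive two-sided permutation p for |mean(x) - mean(y)|."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)
    observed = abs(np.mean(x) - np.mean(y))
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(np.mean(gx) - np.mean(gy)) >= observed - 1e-12:
            count += 1
    return count / total
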