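"""Percentile ranges, five-category quantization, heatmap ordering, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytofuse as cf
from cytofuse.cluster import ClusterStats
from cytofuse.errors import SpecError
from cytofuse.phenotype import (
    DEFAULT_ANNOTATION_RULES,
    AnnotationRule,
    CategoricalHeatmap,
    MarkerRange,
    annotate_populations,
    build_heatmap,
    categorize,
    compute_marker_ranges,
    order_heatmap,
)

import oracles


def _profile(x, markers):
    return cf.CytometricProfile(np.asarray(x, dtype=float), list(markers), transformed=True)


def _stats(mean_of_medians: pd.DataFrame, totals) -> ClusterStats:
    total = pd.Series(totals, index=mean_of_medians.index, name="total")
    counts = total.to_frame("i1")
    medians = mean_of_medians.copy()
    medians.index = pd.MultiIndex.from_product([mean_of_medians.index, ["i1"]])
    return ClusterStats(counts=counts, medians=medians,
                        mean_of_medians=mean_of_medians, total=total)


class TestMarkerRanges:
    def test_uniform_grid_gives_5_and_95(self):
        p = _profile(np.arange(101, dtype=float).reshape(-1, 1), ["m"])
        (r,) = compute_marker_ranges([p], ["m"])
        assert r.low == 5.0 and r.high == 95.0

    def test_constant_marker_degenerates(self):
        p = _profile(np.full((20, 1), 7.0), ["m"])
        (r,) = compute_marker_ranges([p], ["m"])
        assert r.low == r.high == 7.0

    def test_standard_normal_quantiles(self, rng):
        p = _profile(rng.standard_normal((1000, 1)), ["m"])
        (r,) = compute_marker_ranges([p], ["m"])
        assert abs(r.low - (-1.645)) < 0.15
        assert abs(r.high - 1.645) < 0.15

    def test_pools_cells_across_profiles(self):
        a = _profile(np.zeros((50, 1)), ["m"])
        b = _profile(np.ones((50, 1)), ["m"])
        (r,) = compute_marker_ranges([a, b], ["m"])
        assert r.low == 0.0 and r.high == 1.0


class TestCategorize:
    RANGE = MarkerRange("m", 0.0, 10.0)

    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, 1), (3.0, 2), (9.9, 5), (-4.0, 1), (0.0, 1), (10.0, 5), (25.0, 5),
         (2.0, 2), (4.0, 3)],
    )
    def test_bin_arithmetic_and_clamping(self, value, expected):
        assert categorize(value, self.RANGE) == expected

    def test_degenerate_range(self):
        r = MarkerRange("m", 2.0, 2.0)
        assert categorize(1.9, r) == 1
        assert categorize(2.0, r) == 1
        assert categorize(2.1, r) == 5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_monotone_in_the_value(self, v1, v2):
        lo, hi = min(v1, v2), max(v1, v2)
        assert categorize(lo, self.RANGE) <= categorize(hi, self.RANGE)

    def test_uniform_values_fill_categories_evenly(self, rng):
        values = rng.uniform(0.0, 10.0, size=10_000)
        cats = categorize(values, self.RANGE)
        freq = np.bincount(cats, minlength=6)[1:] / values.size
        assert np.all(np.abs(freq - 0.2) < 0.02)


class TestBuildHeatmap:
    def test_small_cluster_rule_boundary(self):
        mm = pd.DataFrame({"m": [5.0, 5.0]}, index=[1, 2])
        stats = _stats(mm, totals=[49, 50])
        ranges = [MarkerRange("m", 0.0, 10.0)]
        hm = build_heatmap(stats, ranges, min_cells=50)
        assert hm.unassigned.loc[1] and not hm.unassigned.loc[2]
        assert pd.isna(hm.categories.loc[1, "m"])
        assert hm.categories.loc[2, "m"] == 3

    def test_value_above_high_is_bright(self):
        mm = pd.DataFrame({"m": [12.0]}, index=[1])
        hm = build_heatmap(_stats(mm, [100]), [MarkerRange("m", 0.0, 10.0)])
        assert hm.categories.loc[1, "m"] == 5


class TestOrderHeatmap:
    def _heatmap(self, matrix, markers, unassigned=None):
        cats = pd.DataFrame(matrix, columns=markers).astype("Int64")
        flags = pd.Series(False, index=cats.index) if unassigned is None else unassigned
        return CategoricalHeatmap(categories=cats, unassigned=flags, min_cells=50)

    def test_orders_are_permutations(self, rng):
        matrix = rng.integers(1, 6, size=(6, 4))
        hm = self._heatmap(matrix, ["a", "b", "c", "d"])
        rows, bb, spec = order_heatmap(hm, ["a", "b"])
        assert sorted(rows) == list(range(6))
        assert sorted(bb) == ["a", "b"] and sorted(spec) == ["c", "d"]

    def test_identical_rows_adjacent_in_the_order(self):
        matrix = [[1, 1, 1], [5, 5, 5], [1, 1, 1]]
        hm = self._heatmap(matrix, ["a", "b", "c"])
        rows, _, _ = order_heatmap(hm, ["a"])
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[0] - pos[2]) == 1

    def test_unassigned_rows_appended_last(self):
        matrix = [[1, 2], [3, 4], [5, 1]]
        flags = pd.Series([False, True, False])
        hm = self._heatmap(matrix, ["a", "b"], unassigned=flags)
        rows, _, _ = order_heatmap(hm, ["a"])
        assert rows[-1] == 1

    def test_linkage_heights_match_complete_linkage_oracle(self, rng):
        from scipy.cluster.hierarchy import linkage

        matrix = rng.integers(1, 6, size=(6, 4)).astype(float)
        got = sorted(linkage(matrix, method="complete", metric="euclidean")[:, 2])
        expected = sorted(oracles.complete_linkage_heights(matrix))
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_single_assigned_cluster_identity_order(self):
        hm = self._heatmap([[1, 2]], ["a", "b"])
        rows, _, _ = order_heatmap(hm, ["a"])
        assert rows == [0]


class TestAnnotate:
    def _heatmap(self, rows: dict, markers, unassigned=None):
        cats = pd.DataFrame.from_dict(rows, orient="index", columns=markers).astype("Int64")
        flags = pd.Series(False, index=cats.index) if unassigned is None else unassigned
        return CategoricalHeatmap(categories=cats, unassigned=flags, min_cells=50)

    MARKERS = ["CD3", "CD19", "CD66", "CD14", "CD11c", "CD123", "HLADR", "GranzymeB"]

    def test_t_cell_rule(self):
        hm = self._heatmap({1: [5, 1, 1, 1, 1, 1, 1, 1]}, self.MARKERS)
        assert annotate_populations(hm).loc[1] == "T cell"

    def test_all_negative_is_unannotated(self):
        hm = self._heatmap({1: [1] * 8}, self.MARKERS)
        assert annotate_populations(hm).loc[1] == "unannotated"

    def test_unassigned_rows_stay_unassigned(self):
        flags = pd.Series({1: True})
        hm = self._heatmap({1: [5, 1, 1, 1, 1, 1, 1, 1]}, self.MARKERS, unassigned=flags)
        assert annotate_populations(hm).loc[1] == "unassigned"

    def test_rule_with_missing_marker_rejected(self):
        hm = self._heatmap({1: [1] * 8}, self.MARKERS)
        rules = (AnnotationRule("ghost", (("CD999", ">=", 4),)),)
        with pytest.raises(SpecError):
            annotate_populations(hm, rules)

    def test_first_matching_rule_wins(self):
        # CD66 bright beats the T-cell rule even with CD3 high
        hm = self._heatmap({1: [5, 1, 5, 1, 1, 1, 1, 1]}, self.MARKERS)
        assert annotate_populations(hm).loc[1] == "PMN"


class TestPresetDirectionality:
    def test_preset_populations_all_recovered(self, preset_analysis):
        found = set(preset_analysis["populations"].unique())
        expected = {"T cell", "B cell", "NK cell", "Monocyte", "mDC", "pDC",
                    "PMN", "Basophil"}
        assert expected <= found

    def test_hiv_enriched_monocytes_have_strictly_higher_shifted_categories(self, preset_analysis):
        hm = preset_analysis["heatmap"]
        pops = preset_analysis["populations"]
        etc = preset_analysis["etc"]
        mono = pops[pops == "Monocyte"].index
        hiv_clusters = [c for c in mono if etc.loc[c, "label"] == "enriched_HIV"]
        hea_clusters = [c for c in mono if etc.loc[c, "label"] == "enriched_HEA"]
        assert hiv_clusters and hea_clusters
        for marker in cf.HIV_SHIFTED_MARKERS:
            assert (hm.categories.loc[hiv_clusters, marker].min()
                    > hm.categories.loc[hea_clusters, marker].max())
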