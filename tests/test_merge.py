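"""Backbone matching, merging, accounting and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytofuse as cf
from cytofuse.errors import FormatError, MarkerLookupError, SpecError

import oracles

BB3 = cf.BackboneSpec(markers=("a", "b", "c"), threshold=3.0)


def _profile(x, markers=("a", "b", "c")):
    return cf.CytometricProfile(np.asarray(x, dtype=float), list(markers), transformed=True)


class TestBackboneDistance:
    def test_identical_rows_give_zero(self):
        row = {"a": 1.0, "b": 2.0, "c": 3.0}
        assert cf.backbone_distance(row, dict(row), BB3) == 0.0

    def test_three_four_five_triangle(self):
        spec = cf.BackboneSpec(markers=("a", "b"))
        assert cf.backbone_distance({"a": 0, "b": 0}, {"a": 3, "b": 4}, spec) == 5.0

    def test_missing_backbone_marker_is_a_lookup_error(self):
        with pytest.raises(MarkerLookupError):
            cf.backbone_distance({"a": 1, "b": 2}, {"a": 1, "b": 2}, BB3)

    def test_matches_sum_of_squares_oracle(self, rng):
        spec = cf.BackboneSpec(markers=tuple("abcdef"))
        for _ in range(100):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            got = cf.backbone_distance(dict(zip("abcdef", a)), dict(zip("abcdef", b)), spec)
            assert abs(got - oracles.euclidean(a, b)) < 1e-9


class TestMatchProfiles:
    def test_identical_profiles_match_completely(self, rng):
        x = rng.normal(size=(10, 3))
        match = cf.match_profiles(_profile(x), _profile(x.copy()), BB3)
        assert match.n_pairs == 10
        assert all(d == 0.0 for _, _, d in match.pairs)
        assert all(i == j for i, j, _ in match.pairs)
        assert match.unmatched_a.size == match.unmatched_b.size == 0

    def test_threshold_below_minimum_distance_matches_nothing(self):
        a = _profile([[0.0, 0.0, 0.0]])
        b = _profile([[10.0, 0.0, 0.0]])
        match = cf.match_profiles(a, b, cf.BackboneSpec(("a", "b", "c"), threshold=1.0))
        assert match.n_pairs == 0
        assert list(match.unmatched_a) == [0] and list(match.unmatched_b) == [0]

    def test_agrees_with_exhaustive_oracle_on_small_instances(self, rng):
        for _ in range(60):
            na, nb = rng.integers(1, 9, size=2)
            xa = rng.normal(size=(na, 3))
            xb = rng.normal(size=(nb, 3))
            threshold = float(rng.uniform(0.5, 3.0))
            spec = cf.BackboneSpec(("a", "b", "c"), threshold)
            got = {(i, j) for i, j, _ in cf.match_profiles(_profile(xa), _profile(xb), spec).pairs}
            assert got == oracles.mutual_nn_pairs(xa, xb, threshold)

    def test_matching_is_symmetric(self, rng):
        xa = rng.normal(size=(30, 3))
        xb = rng.normal(size=(25, 3))
        fwd = {(i, j) for i, j, _ in cf.match_profiles(_profile(xa), _profile(xb), BB3).pairs}
        rev = {(j, i) for i, j, _ in cf.match_profiles(_profile(xb), _profile(xa), BB3).pairs}
        assert fwd == rev

    def test_all_matched_distances_within_threshold(self, rng):
        xa = rng.normal(size=(50, 3)) * 2
        xb = rng.normal(size=(40, 3)) * 2
        spec = cf.BackboneSpec(("a", "b", "c"), threshold=1.5)
        match = cf.match_profiles(_profile(xa), _profile(xb), spec)
        assert all(d <= 1.5 for _, _, d in match.pairs)

    def test_untransformed_profiles_rejected(self):
        a = cf.CytometricProfile(np.zeros((2, 3)), ["a", "b", "c"])
        with pytest.raises(SpecError):
            cf.match_profiles(a, a, BB3)


class TestMergeTwo:
    def test_backbone_averaged_specific_copied(self):
        a = cf.CytometricProfile(np.array([[1.0, 7.0]]), ["bb", "onlyA"], transformed=True)
        b = cf.CytometricProfile(np.array([[3.0, 9.0]]), ["bb", "onlyB"], transformed=True)
        match = cf.match_profiles(a, b, cf.BackboneSpec(("bb",), threshold=5.0))
        merged = cf.merge_two(a, b, match, ("bb",))
        assert merged.markers == ["bb", "onlyA", "onlyB"]
        np.testing.assert_allclose(merged.events, [[2.0, 7.0, 9.0]])

    def test_identical_backbone_values_preserved(self, rng):
        x = rng.normal(size=(5, 2))
        a = _profile(x, ("bb1", "bb2"))
        b = _profile(x.copy(), ("bb1", "bb2"))
        spec = cf.BackboneSpec(("bb1", "bb2"))
        merged = cf.merge_two(a, b, cf.match_profiles(a, b, spec), spec.markers)
        np.testing.assert_allclose(np.sort(merged.events, axis=0), np.sort(x, axis=0))

    def test_specific_marker_collision_rejected(self):
        a = cf.CytometricProfile(np.ones((1, 2)), ["bb", "dup"], transformed=True)
        b = cf.CytometricProfile(np.ones((1, 2)), ["bb", "dup"], transformed=True)
        match = cf.match_profiles(a, b, cf.BackboneSpec(("bb",)))
        with pytest.raises(FormatError):
            cf.merge_two(a, b, match, ("bb",))


class TestMergePanelset:
    def test_zero_noise_three_panel_split_recovers_the_source(self, rng):
        spec = cf.make_hiv_cohort_preset(seed=21, n_events=400)
        full, truth = cf.generate_individual(spec, "PAT-2")
        panelset = cf.split_panels(full, truth, spec.panels, backbone_noise_sd=0.0, seed=1)
        result = cf.merge_panelset(panelset)
        assert result.n_merged == 400
        assert result.n_excluded == 0
        assert len(result.merged.markers) == 72
        order = np.argsort(result.merged.event_ids)
        source = cf.subset_markers(full, result.merged.markers)
        np.testing.assert_allclose(result.merged.events[order], source.events, atol=1e-12)

    def test_three_identical_profiles_merge_losslessly(self, rng):
        x = rng.normal(size=(20, 2))
        profiles = {
            pid: _profile(x.copy(), ("u", "v")) for pid in ("P1", "P2", "P3")
        }
        panelset = cf.PanelSet("s", profiles, ("u", "v"))
        result = cf.merge_panelset(panelset)
        assert result.n_merged == 20
        assert result.n_excluded == 0

    def test_provenance_chains_cover_all_panels(self, rng):
        spec = cf.make_hiv_cohort_preset(seed=22, n_events=200)
        full, truth = cf.generate_individual(spec, "HEA-3")
        panelset = cf.split_panels(full, truth, spec.panels, backbone_noise_sd=0.02, seed=2)
        result = cf.merge_panelset(panelset)
        for prov in result.provenance:
            assert set(prov) == {"#A", "#B", "#C"}

    def test_unknown_panel_in_order_rejected(self, rng):
        x = rng.normal(size=(5, 1))
        profiles = {p: _profile(x, ("u",)) for p in ("P1", "P2")}
        panelset = cf.PanelSet("s", profiles, ("u",))
        with pytest.raises(SpecError):
            cf.merge_panelset(panelset, order=["P1", "nope"])

    def test_merged_never_exceeds_smallest_input(self, rng):
        for trial in range(5):
            profiles = {
                f"P{k}": _profile(rng.normal(size=(int(rng.integers(5, 30)), 2)), ("u", "v"))
                for k in range(3)
            }
            panelset = cf.PanelSet("s", profiles, ("u", "v"))
            result = cf.merge_panelset(
                panelset, spec=cf.BackboneSpec(("u", "v"), threshold=1.0)
            )
            assert result.n_merged <= min(result.n_input.values())


class TestAccounting:
    def test_reference_counts_reproduce_published_exclusions(self):
        # excluded = sum(inputs) - 3 * merged, donor by donor
        expected = {
            "HEA-1": 151_146, "HEA-2": 40_990, "HEA-3": 34_946,
            "PAT-1": 177_397, "PAT-2": 62_049, "PAT-3": 13_573,
        }
        table = cf.load_reference_merge_counts()
        for sample, row in table.iterrows():
            n_input = {"#A": row.n_A, "#B": row.n_B, "#C": row.n_C}
            assert cf.merge_accounting(n_input, row.n_merged) == expected[sample]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=10**6), min_size=2, max_size=5),
        st.integers(min_value=0, max_value=10**6),
    )
    def test_accounting_identity_holds_generally(self, inputs, merged):
        merged = min(merged, min(inputs))
        n_input = {f"P{i}": n for i, n in enumerate(inputs)}
        excluded = cf.merge_accounting(n_input, merged)
        assert excluded == sum(inputs) - len(inputs) * merged

    def test_report_excluded_rederivable_from_other_columns(self, rng):
        x = rng.normal(size=(15, 2))
        profiles = {p: _profile(x + rng.normal(size=x.shape) * 0.01, ("u", "v"))
                    for p in ("P1", "P2")}
        panelset = cf.PanelSet("s", profiles, ("u", "v"))
        result = cf.merge_panelset(panelset)
        report = cf.merge_report(result, sample_id="s")
        inputs = report["n_cells"].dropna().astype(int)
        combined = report[report["profile"] == "P1+P2"].iloc[0]
        assert combined["n_excluded"] == inputs.sum() - 2 * combined["n_merged"]

    def test_zero_event_inputs_give_all_zero_report(self):
        profiles = {p: cf.CytometricProfile(np.empty((0, 2)), ["u", "v"], transformed=True)
                    for p in ("P1", "P2")}
        panelset = cf.PanelSet("s", profiles, ("u", "v"))
        report = cf.merge_report(cf.merge_panelset(panelset))
        combined = report.iloc[-1]
        assert combined["n_merged"] == 0 and combined["n_excluded"] == 0
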