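"""Bundled reference tables.

The merge-accounting reference is the published per-panel and merged cell
count table of a six-donor (three healthy, three HIV-positive on
antiretroviral therapy) three-panel mass-cytometry study -- the study design
this package's synthetic preset emulates.  Only cell counts are bundled, no
event-level data; they exercise the merge accounting identities at the
scale of a real experiment.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_merge_counts", "reference_merge_summary"]

# sample, condition, per-panel cell counts (#A, #B, #C), merged cell count
_REFERENCE_ROWS = [
    ("HEA-1", "HEA", 237_039, 192_201, 139_218, 139_104),
    ("HEA-2", "HEA", 249_773, 249_003, 229_388, 229_058),
    ("HEA-3", "HEA", 128_604, 112_246, 103_360, 103_088),
    ("PAT-1", "HIV", 221_756, 162_754, 104_389, 103_834),
    ("PAT-2", "HIV", 254_188, 229_615, 211_915, 211_223),
    ("PAT-3", "HIV", 77_907, 68_757, 68_749, 67_280),
]


def load_reference_merge_counts() -> pd.DataFrame:
    """Per-donor cell counts before and after the three-panel merge.

    Columns: ``condition``, ``n_A``, ``n_B``, ``n_C`` (cells per panel) and
    ``n_merged`` (cells in the combined 72-marker profile), indexed by donor.
    """
    frame = pd.DataFrame(
        _REFERENCE_ROWS, columns=["sample", "condition", "n_A", "n_B", "n_C", "n_merged"]
    ).set_index("sample")
    return frame


def reference_merge_summary() -> pd.Series:
    """Summary statistics of the reference merged counts.

    Means are rounded half away from zero to whole cells, matching how such
    counts are reported.
    """
    frame = load_reference_merge_counts()

    def _round_half_away(x: float) -> int:
        import math

        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))

    merged = frame["n_merged"]
    smallest = frame[["n_A", "n_B", "n_C"]].min(axis=1)
    return pd.Series(
        {
            "mean_merged": _round_half_away(merged.mean()),
            "mean_merged_HEA": _round_half_away(merged[frame.condition == "HEA"].mean()),
            "mean_merged_HIV": _round_half_away(merged[frame.condition == "HIV"].mean()),
            "min_merge_efficiency": float((merged / smallest).min()),
        }
    )
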