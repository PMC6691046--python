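"""Cytometric profile container, I/O and the arcsinh intensity transform.

A :class:`CytometricProfile` is the package's event-level container: a dense
cells x markers matrix of intensities plus the marker names and the sample /
panel identity.  Mass-cytometry intensities are variance-stabilised with the
inverse hyperbolic sine transform ``asinh(x / cofactor)`` (cofactor 5 by
convention for CyTOF data) before any distance computation, clustering or
statistics; the container tracks the transform state explicitly so it cannot
be applied twice by accident.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fcs
from .errors import FormatError, MarkerLookupError, SpecError, StateError

__all__ = [
    "CytometricProfile",
    "PanelDefinition",
    "PanelSet",
    "TransformSpec",
    "read_profile",
    "write_profile",
    "arcsinh_transform",
    "inverse_arcsinh",
    "subset_markers",
]


@dataclass(frozen=True)
class TransformSpec:
    """Arcsinh transform specification; ``cofactor`` must be positive."""

    cofactor: float = 5.0

    def __post_init__(self):
        if not self.cofactor > 0:
            raise SpecError(f"cofactor must be > 0, got {self.cofactor}")


@dataclass(frozen=True)
class PanelDefinition:
    """An antibody panel: its marker list and the shared backbone subset."""

    panel_id: str
    markers: tuple[str, ...]
    backbone: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "backbone", tuple(self.backbone))
        if len(set(self.markers)) != len(self.markers):
            raise SpecError(f"panel {self.panel_id}: duplicate marker names")
        missing = set(self.backbone) - set(self.markers)
        if missing:
            raise SpecError(
                f"panel {self.panel_id}: backbone markers not in panel: {sorted(missing)}"
            )

    @property
    def specific(self) -> tuple[str, ...]:
        """Markers measured only by this panel (panel order, backbone removed)."""
        bb = set(self.backbone)
        return tuple(m for m in self.markers if m not in bb)


@dataclass
class CytometricProfile:
    """Event x marker matrix of intensities for one acquisition.

    Parameters
    ----------
    events
        Real-valued matrix, one row per cell, one column per marker.
    markers
        Unique marker names, one per column.
    sample_id, panel_id
        Identity of the biological sample and the antibody panel.
    transformed
        True once intensities are in arcsinh units.
    event_ids
        Optional per-row identifiers.  Used by the synthetic cohort
        generator to carry ground-truth cell identity; analysis code never
        reads them.
    """

    events: np.ndarray
    markers: list[str]
    sample_id: str = ""
    panel_id: str = ""
    transformed: bool = False
    event_ids: np.ndarray | None = None

    def __post_init__(self):
        self.events = np.atleast_2d(np.asarray(self.events, dtype=np.float64))
        if self.events.size == 0:
            self.events = self.events.reshape(0, len(self.markers))
        self.markers = list(self.markers)
        if len(set(self.markers)) != len(self.markers):
            dupes = sorted({m for m in self.markers if self.markers.count(m) > 1})
            raise FormatError(f"duplicate marker names: {dupes}")
        if self.events.shape[1] != len(self.markers):
            raise FormatError(
                f"{self.events.shape[1]} columns but {len(self.markers)} marker names"
            )
        if self.event_ids is not None:
            self.event_ids = np.asarray(self.event_ids)
            if self.event_ids.shape[0] != self.events.shape[0]:
                raise FormatError("event_ids length does not match event count")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def marker_index(self, markers) -> np.ndarray:
        """Column indices of the requested markers (raises on unknown names)."""
        pos = {m: i for i, m in enumerate(self.markers)}
        try:
            return np.asarray([pos[m] for m in markers], dtype=np.intp)
        except KeyError as exc:
            raise MarkerLookupError(exc.args[0]) from None

    def values(self, markers) -> np.ndarray:
        """Event values restricted to ``markers``, in the requested order."""
        return self.events[:, self.marker_index(markers)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=self.markers)


@dataclass
class PanelSet:
    """The profiles of one biological sample measured under different panels.

    Every profile must contain the full backbone marker set; the backbone is
    the coordinate system in which cross-panel cell matching happens.
    """

    sample_id: str
    profiles: dict[str, CytometricProfile]
    backbone: tuple[str, ...]

    def __post_init__(self):
        self.backbone = tuple(self.backbone)
        if len(self.profiles) < 2:
            raise SpecError("a PanelSet needs at least two panels")
        for pid, prof in self.profiles.items():
            missing = set(self.backbone) - set(prof.markers)
            if missing:
                raise SpecError(
                    f"panel {pid} is missing backbone markers: {sorted(missing)}"
                )

    @property
    def panel_ids(self) -> list[str]:
        return list(self.profiles)


def read_profile(path, format: str = "tsv", sample_id: str = "", panel_id: str = "") -> CytometricProfile:
    """Read a cytometric profile from a TSV event table or a list-mode FCS file.

    The TSV dialect is: first row marker names, one event per subsequent row,
    tab separated, no index column.  The returned profile has the transformed
    flag unset and preserves the stored event order.
    """
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        markers = header.split("\t") if header else []
        if len(set(markers)) != len(markers):
            dupes = sorted({m for m in markers if markers.count(m) > 1})
            raise FormatError(f"duplicate marker names in {path}: {dupes}")
        frame = pd.read_csv(path, sep="\t", header=None, names=markers, skiprows=1,
                            dtype=np.float64)
        events = frame.to_numpy(dtype=np.float64).reshape(len(frame), len(markers))
    elif format == "fcs":
        events, markers = _fcs.read_fcs(path)
    else:
        raise SpecError(f"unknown profile format: {format!r}")
    return CytometricProfile(
        events=events, markers=markers, sample_id=sample_id, panel_id=panel_id
    )


def write_profile(profile: CytometricProfile, path, format: str = "tsv") -> None:
    """Write a profile so that :func:`read_profile` recovers it.

    TSV round-trips to full float precision; FCS stores 32-bit floats and
    round-trips to single precision.
    """
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(profile.markers) + "\n")
            np.savetxt(fh, profile.events.reshape(profile.n_events, len(profile.markers)),
                       delimiter="\t", fmt="%.10g")
    elif format == "fcs":
        _fcs.write_fcs(path, profile.events, profile.markers)
    else:
        raise SpecError(f"unknown profile format: {format!r}")


def arcsinh_transform(profile: CytometricProfile, spec: TransformSpec = TransformSpec()) -> CytometricProfile:
    """Apply ``asinh(x / cofactor)`` to every intensity.

    The transform is strictly monotone and invertible
    (``x = cofactor * sinh(y)``); applying it to an already-transformed
    profile raises :class:`StateError`.
    """
    if profile.transformed:
        raise StateError("profile is already arcsinh-transformed")
    out = replace_events(profile, np.arcsinh(profile.events / spec.cofactor))
    out.transformed = True
    return out


def inverse_arcsinh(profile: CytometricProfile, spec: TransformSpec = TransformSpec()) -> CytometricProfile:
    """Undo :func:`arcsinh_transform` (``x = cofactor * sinh(y)``)."""
    if not profile.transformed:
        raise StateError("profile is not arcsinh-transformed")
    out = replace_events(profile, spec.cofactor * np.sinh(profile.events))
    out.transformed = False
    return out


def replace_events(profile: CytometricProfile, events: np.ndarray) -> CytometricProfile:
    """Copy of ``profile`` with a new event matrix (same markers/identity)."""
    return CytometricProfile(
        events=np.asarray(events, dtype=np.float64),
        markers=list(profile.markers),
        sample_id=profile.sample_id,
        panel_id=profile.panel_id,
        transformed=profile.transformed,
        event_ids=None if profile.event_ids is None else profile.event_ids.copy(),
    )


def subset_markers(profile: CytometricProfile, markers) -> CytometricProfile:
    """Restrict (and reorder) the profile columns to ``markers``; rows unchanged."""
    idx = profile.marker_index(markers)
    return CytometricProfile(
        events=profile.events[:, idx],
        markers=list(markers),
        sample_id=profile.sample_id,
        panel_id=profile.panel_id,
        transformed=profile.transformed,
        event_ids=None if profile.event_ids is None else profile.event_ids.copy(),
    )
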