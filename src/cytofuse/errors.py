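"""Exception hierarchy for cytofuse."""


class CytofuseError(Exception):
    """Base class for all cytofuse errors."""


class FormatError(CytofuseError):
    """A file or profile violates a structural rule (e.g. duplicate marker names)."""


class SpecError(CytofuseError):
    """A configuration or specification object is invalid."""


class StateError(CytofuseError):
    """An operation was applied in an invalid state (e.g. double transformation)."""


class MarkerLookupError(CytofuseError, KeyError):
    """A requested marker is not present in a profile."""

    def __init__(self, marker: str):
        super().__init__(f"marker not present in profile: {marker!r}")
        self.marker = marker
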