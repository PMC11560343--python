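"""Exception hierarchy for the jaw-disparity pipeline.

All errors derive from :class:`JawdispError` so callers (and the CLI) can
catch pipeline failures with a single except clause while still
distinguishing bad inputs from degenerate geometry.
"""


class JawdispError(Exception):
    """Base class for all package errors."""


class InputError(JawdispError):
    """Invalid input values (non-finite, out of range, wrong shape)."""


class DegenerateGeometryError(JawdispError):
    """Landmark configuration makes a measurement undefined (zero lever)."""


class MissingLandmarkError(JawdispError):
    """One or more required landmarks are absent from a specimen."""

    def __init__(self, specimen_id: str, missing: list[str]):
        self.specimen_id = specimen_id
        self.missing = list(missing)
        super().__init__(
            f"specimen {specimen_id!r} is missing landmarks: {', '.join(self.missing)}"
        )


class CharacterParseError(JawdispError):
    """Character-matrix file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoComparableCharactersError(JawdispError):
    """A taxon pair shares no non-missing characters; Gower is undefined."""

    def __init__(self, taxon_a: str, taxon_b: str):
        self.pair = (taxon_a, taxon_b)
        super().__init__(
            f"taxa {taxon_a!r} and {taxon_b!r} have no comparable characters"
        )
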