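"""Exception hierarchy shared across the package."""


class DESError(Exception):
    """Base class for all dessound errors."""


class UnknownGroupError(DESError, KeyError):
    """A group token is absent from the active group-parameter table."""

    def __str__(self) -> str:  # KeyError would repr() the message
        return Exception.__str__(self)


class ValidityRangeError(DESError, ValueError):
    """Inputs fall outside the validity range of a correlation."""


class DataFormatError(DESError, ValueError):
    """A file or record does not match the documented schema."""


class FixtureIntegrityError(DESError):
    """A bundled reference table fails its checksum pin."""
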