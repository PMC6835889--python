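"""Exception hierarchy shared across the package."""


class UrinormError(Exception):
    """Base class for all package errors."""


class SchemaError(UrinormError):
    """Input files disagree with each other or with the expected layout."""


class ValidationError(UrinormError):
    """A table or configuration violates an invariant."""


class FeatureNotFoundError(UrinormError):
    """No feature matched the (m/z, rt) query window."""

    def __init__(self, message: str, closest: str | None = None):
        super().__init__(message)
        self.closest = closest
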