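"""Exception hierarchy."""


class SumdKitError(Exception):
    """Base class for all package errors."""


class ParameterError(SumdKitError, ValueError):
    """A physical or algorithmic parameter violates its contract."""


class SelectionError(SumdKitError, KeyError):
    """An atom/residue selection resolved to nothing or named a missing id."""


class GeometryError(SumdKitError, ValueError):
    """A geometric operation received a degenerate configuration."""


class IntegrationError(SumdKitError, RuntimeError):
    """The integrator produced non-finite coordinates."""


class FormatError(SumdKitError, ValueError):
    """A structure or trajectory file violates its format contract."""
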