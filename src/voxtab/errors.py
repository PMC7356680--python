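"""Exception hierarchy shared across the package."""


class VoxtabError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VoxtabError, ValueError):
    """An input violates a documented precondition or schema constraint."""


class InconsistentGeometryError(VoxtabError, ValueError):
    """Mass, volume and density imply a physically impossible geometry."""


class DegenerateFitError(VoxtabError, RuntimeError):
    """A model fit is unidentifiable for the supplied data."""
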