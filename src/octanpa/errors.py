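"""Exception hierarchy for octanpa.

All package-specific failures derive from :class:`OctanpaError` so callers can
catch one base class; subclasses distinguish I/O format problems, metadata
problems, contract (shape/role) violations, degenerate numeric inputs, bad
parameters, manifest validation and phantom generation failures.
"""


class OctanpaError(Exception):
    """Base class for all octanpa errors."""


class FormatError(OctanpaError):
    """A file exists but its content violates the expected format."""


class MetadataError(OctanpaError):
    """Required physical metadata (e.g. pixel size) is missing or invalid."""


class ContractError(OctanpaError):
    """An operation's input contract is violated (shape/role mismatch)."""


class DegenerateInputError(OctanpaError):
    """Numerically degenerate input, e.g. a flat image with no dynamic range."""


class ParameterError(OctanpaError):
    """A pipeline parameter is outside its valid domain."""


class ManifestError(OctanpaError):
    """A visit manifest fails validation."""


class GenerationError(OctanpaError):
    """Synthetic phantom generation could not satisfy its constraints."""
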