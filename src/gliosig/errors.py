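"""Exception hierarchy shared across the pipeline stages."""


class GliosigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GliosigError):
    """A file does not conform to its expected on-disk format."""


class ParameterError(GliosigError, ValueError):
    """A parameter or specification value violates its invariants."""


class DegenerateDataError(GliosigError):
    """Input data lack the structure an operation requires (e.g. all values identical)."""


class DependencyError(GliosigError):
    """A pipeline stage is missing an upstream output."""
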