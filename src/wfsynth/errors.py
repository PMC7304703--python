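"""Exception hierarchy.

Every error raised by the library derives from :class:`WfsynthError` so that
callers (notably the CLI) can distinguish domain failures from bugs.
"""


class WfsynthError(Exception):
    """Base class for all library errors."""


class OntologyFormatError(WfsynthError):
    """The ontology document could not be parsed."""


class ConfigurationError(WfsynthError):
    """A configuration value is missing, malformed, or dangling."""


class DisjointnessError(WfsynthError):
    """A taxonomy class is reachable from more than one dimension root."""


class DimensionMismatchError(WfsynthError):
    """Two terms from different dimensions were compared."""


class UnresolvedTermError(WfsynthError):
    """A term reference does not resolve (or resolves ambiguously)."""


class AnnotationSchemaError(WfsynthError):
    """A tool-annotation document violates the documented schema."""


class SpecificationError(WfsynthError):
    """A workflow specification document is invalid."""


class CatalogError(WfsynthError):
    """An unknown constraint template was requested."""


class TemplateSignatureError(WfsynthError):
    """Constraint arguments do not match the template signature."""


class EncodingError(WfsynthError):
    """The synthesis problem cannot be encoded (e.g. empty tool set)."""


class EngineError(WfsynthError):
    """The SAT engine failed or produced an inconsistent model."""


class ExportError(WfsynthError):
    """A solution could not be exported (e.g. bad command template)."""


class OracleSizeError(WfsynthError):
    """The brute-force oracle guard was exceeded."""
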