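"""Exception hierarchy.

All package errors derive from :class:`CgindivError` so callers can catch
everything with one clause; each leaf also derives from the closest builtin
(``ValueError`` / ``IOError``) so untargeted code behaves sensibly.
"""


class CgindivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CgindivError, ValueError):
    """A tabular input file does not have the expected shape or columns."""


class ValidationError(CgindivError, ValueError):
    """A domain invariant is violated (duplicate ids, missing traits, ...)."""


class CoverageError(CgindivError, ValueError):
    """A partition does not cover exactly the alive particles of a population."""


class DomainError(CgindivError, ValueError):
    """An argument is outside an operation's mathematical domain."""


class ConfigurationError(CgindivError, ValueError):
    """A run configuration or update rule is invalid or incomplete."""


class ResourceError(CgindivError, RuntimeError):
    """A computational guard (e.g. bipartition enumeration size) was exceeded."""


class MappingRuleError(CgindivError, ValueError):
    """The synchronous particle->collective event mapping is violated."""
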