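"""Exception types shared across morfpath modules."""


class MorfpathError(Exception):
    """Base class for all morfpath-specific errors."""


class AnnotationFormatError(MorfpathError):
    """An input annotation file could not be parsed; the message names the
    offending line or feature."""


class UndefinedMetricError(MorfpathError):
    """A score metric was requested on counts for which it is undefined
    (e.g. specificity with zero predictions)."""


class DegenerateTableError(MorfpathError):
    """A contingency table has a zero marginal, so the chi-square test is
    undefined."""


class PlacementError(MorfpathError):
    """Simulated ORFs could not be placed on a genome of the requested size."""


class ConfigurationError(MorfpathError):
    """A workflow or path configuration is inconsistent (missing engine,
    mismatched panels, ...)."""
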