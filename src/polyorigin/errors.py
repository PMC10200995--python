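"""Exception hierarchy shared across the pipeline stages."""


class PolyOriginError(Exception):
    """Base class for all package-specific errors."""


class ScenarioError(PolyOriginError):
    """Invalid simulation scenario configuration."""


class MappingError(PolyOriginError):
    """A leaf label or taxon could not be resolved against the section map."""


class NewickParseError(PolyOriginError):
    """Malformed Newick input."""


class RootingError(PolyOriginError):
    """Outgroup-based rooting failed (zero or multiple outgroup leaves)."""


class AssignmentError(PolyOriginError):
    """Origin assignment is impossible (e.g. a tree without diploid leaves)."""


class InsufficientDataError(PolyOriginError):
    """Too few usable observations for a statistical estimate."""


class NotEvaluableError(PolyOriginError):
    """A statistic is undefined on the given input (distinct from zero)."""
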