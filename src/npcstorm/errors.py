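"""Exception hierarchy shared across the pipeline."""


class NPCStormError(Exception):
    """Base class for all package errors."""


class FormatError(NPCStormError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class ParseError(NPCStormError):
    """A cell could not be parsed; carries the offending row number."""


class GeometryError(NPCStormError):
    """Invalid polygon, mask containment violation, or zero area."""


class ParameterError(NPCStormError):
    """A parameter is outside its valid range."""


class DensityError(NPCStormError):
    """Dart-throwing placement failed; density/min_separation incompatible."""


class DriftCorrectionError(NPCStormError):
    """Drift estimation failed (e.g. under-populated temporal bin)."""


class CoverageError(NPCStormError):
    """A record's frame lies outside the drift track's coverage."""


class DegenerateClusterError(NPCStormError):
    """A cluster has too few members to summarize."""


class FitError(NPCStormError):
    """Curve fit failed or produced an unusable parameter."""


class DomainError(NPCStormError):
    """A derived quantity is requested outside its mathematical domain."""


class DegenerateVarianceError(NPCStormError):
    """Zero within-group variance with unequal means: t undefined."""


class SchemaError(NPCStormError):
    """A results table is missing a required column."""
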