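"""Exception hierarchy for crossrppa."""


class CrossRppaError(Exception):
    """Base class for all package errors."""


class DesignError(CrossRppaError):
    """Invalid study design (empty factor, bad replicate count, ...)."""


class ConfigError(CrossRppaError):
    """Invalid configuration value or unknown configuration key."""


class SchemaError(CrossRppaError):
    """A table does not conform to its expected schema."""


class AlignmentError(CrossRppaError):
    """Sample sets of the platforms to be integrated do not match."""


class AnnotationError(CrossRppaError):
    """Antibody annotation is missing, ambiguous or self-contradictory."""
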