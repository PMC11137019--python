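"""Exception hierarchy shared across the pipeline stages."""


class GpcrBiasError(ValueError):
    """Base class for all contract violations raised by this package."""


class InvalidParameterError(GpcrBiasError):
    """Model parameters are non-finite or violate their invariants."""


class InvalidSpecError(GpcrBiasError):
    """A simulation spec violates its invariants (e.g. n < 2)."""


class ConstructionError(GpcrBiasError):
    """A designed synthetic fixture cannot be realized as requested."""


class InsufficientDataError(GpcrBiasError):
    """Too few distinct concentrations (or points) to attempt a fit."""


class InvalidReferenceError(GpcrBiasError):
    """Reference-normalization denominator is non-positive."""


class InvalidBasalError(GpcrBiasError):
    """Percent-of-basal denominator is non-positive."""


class InvalidDispersionError(GpcrBiasError):
    """A standard error or SD is non-positive where positivity is required."""


class InactiveInputError(GpcrBiasError):
    """Operational fitting was asked to run on data called inactive."""


class ContractError(GpcrBiasError):
    """Mismatched pathways/ligands/subunits across operands."""


class MalformedTrajectoryError(GpcrBiasError):
    """Trajectory frames and annotation table disagree."""


class MissingAnnotationError(GpcrBiasError):
    """A required annotation (e.g. ECL2 loop tags) is absent."""


class SchemaError(GpcrBiasError):
    """An input file does not match the expected column schema."""


class ConfigError(GpcrBiasError):
    """Run configuration violates its invariants."""
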