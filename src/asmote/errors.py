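"""Named exception types raised by validation and pipeline stages."""


class ValidationError(ValueError):
    """Base class for all input-validation failures (CLI maps these to exit 2)."""


class MissingTargetError(ValidationError):
    """The requested target column is absent from the file."""


class TargetCardinalityError(ValidationError):
    """The target column does not have exactly two distinct values."""


class MissingValueError(ValidationError):
    """A cell is empty/NaN; missing data is rejected, not imputed."""


class NonNumericValueError(ValidationError):
    """A feature cell could not be parsed as a number."""


class CategoryValueError(ValidationError):
    """A categorical cell holds a code outside its declared categories."""


class SchemaMismatchError(ValidationError):
    """A schema was supplied but does not cover the file's feature columns."""


class EmptyDatasetError(ValidationError):
    """Zero rows or zero feature columns."""


class SingleClassError(ValidationError):
    """An operation requiring both classes received single-class data."""


class ImbalanceError(ValidationError):
    """Minority/majority counts violate a stage's preconditions (z > r or z = 0)."""


class TooFewMinorityError(ValidationError):
    """Fewer than two minority samples: interpolation is impossible."""


class ConstantTruthError(ValidationError):
    """Relative errors are undefined when the ground truth is constant."""


class UnknownModelError(ValidationError):
    """A model name not in the accepted grid vocabulary."""


class ConfigError(ValidationError):
    """An invalid cross-validation or generator configuration."""
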