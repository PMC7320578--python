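"""Exception types raised by skinpah readers, validators and analyses."""


class SkinpahError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdError(SkinpahError):
    """A sample or taxon identifier occurs more than once."""


class InvalidCountError(SkinpahError):
    """A count cell is negative, non-numeric or non-integer."""


class CohortAlignmentError(SkinpahError):
    """Cohort inputs share no usable samples or subjects."""


class ConfigError(SkinpahError):
    """An analysis-configuration value is out of range or unparsable."""


class EmptyTableError(SkinpahError):
    """An operation received a table with no usable rows or columns."""


class FitError(SkinpahError):
    """A model fit failed to converge; message names bounds and start."""
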