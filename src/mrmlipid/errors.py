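"""Exception hierarchy for the pipeline.

Exit-code mapping used by the CLI: SchemaError and its relatives -> 2,
DegenerateStatisticsError -> 3, I/O problems -> 4.
"""


class MrmLipidError(Exception):
    """Base class for all package errors."""


class LipidNameError(MrmLipidError, ValueError):
    """A lipid species name could not be parsed."""


class SchemaError(MrmLipidError, ValueError):
    """An input table violates its declared schema."""


class NormalizationError(MrmLipidError):
    """A species row has no usable internal-standard intensity."""


class MissingDataError(MrmLipidError):
    """A required (sample, species) measurement is absent."""


class UndefinedCompositionError(MrmLipidError):
    """mol% requested for a class whose total is zero in some sample."""


class DegenerateStatisticsError(MrmLipidError):
    """A statistical operation hit a degenerate configuration it cannot flag."""
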