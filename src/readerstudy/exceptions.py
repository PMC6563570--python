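"""Exception hierarchy for reader-study analysis.

Every error raised by this package derives from :class:`ReaderStudyError`
so callers can catch package failures without masking programming errors.
"""


class ReaderStudyError(Exception):
    """Base class for all readerstudy errors."""


class SchemaError(ReaderStudyError):
    """An input table is missing a required column or has the wrong shape."""


class IntegrityError(ReaderStudyError):
    """Duplicate (reader, case, session) keys or inconsistent records."""


class CompletenessError(ReaderStudyError):
    """A reader-case cell required by the design is absent."""


class AlignmentError(ReaderStudyError):
    """Labels and truth could not be aligned on case_id."""


class UndefinedMetricError(ReaderStudyError):
    """A metric's denominator is zero (e.g. sensitivity with no positives)."""


class DegenerateAgreementError(ReaderStudyError):
    """Expected agreement is 1 so chance-corrected kappa is undefined."""


class DegenerateVarianceError(ReaderStudyError):
    """Paired differences have zero variance; the t statistic is undefined."""


class DegenerateNullWarning(UserWarning):
    """The permutation null is a point mass; the strict-inequality p-value
    is reported but carries no information."""
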