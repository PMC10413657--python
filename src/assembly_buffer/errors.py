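"""Exception hierarchy.

Three families, mirrored by CLI exit codes: parameter/validation problems
(bad arguments, malformed tables), data problems (inputs that fail an
inclusion rule or make a metric undefined), and everything else (internal).
"""


class AssemblyBufferError(Exception):
    """Base class for all package errors."""


class ParameterError(AssemblyBufferError, ValueError):
    """An argument is outside its documented domain."""


class ValidationError(AssemblyBufferError, ValueError):
    """An input object violates a structural invariant."""


class DataError(AssemblyBufferError):
    """Input data fails a scientific inclusion rule or degenerates a metric."""


class InclusionRuleError(DataError):
    """Too few observations survive a stated inclusion filter
    (e.g. fewer than three pathogenic missense positions for clustering)."""


class UndefinedMetricError(DataError):
    """The requested metric is undefined for this input
    (e.g. relative interface location of a zero-area interface)."""


class DegenerateLogError(DataError):
    """A log-ratio statistic hit a non-positive log (mean distance <= 1 Å),
    which flags physically impossible Cα geometry rather than dispersion."""


class DegenerateVarianceError(DataError):
    """A rank test was asked to compare samples with zero rank variance."""


class ZeroCellError(DataError):
    """A 2x2 table has an empty cell, so the odds-ratio SE is undefined.

    No continuity correction is applied automatically; callers that can
    tolerate a zero cell report the raw cross-product odds ratio without a
    confidence interval.
    """


class SchemaMismatchError(ValidationError):
    """A feature table does not match the schema a fitted model expects."""

    def __init__(self, missing: list[str], extra: list[str] | None = None):
        self.missing = list(missing)
        self.extra = list(extra or [])
        msg = f"feature schema mismatch; missing columns: {self.missing}"
        if self.extra:
            msg += f"; unexpected columns: {self.extra}"
        super().__init__(msg)
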