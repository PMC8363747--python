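"""Exception hierarchy for cismr.

All package errors derive from :class:`CismrError` so callers can catch one
type at the CLI boundary; the subclasses distinguish malformed input files,
invalid field values, and allele-harmonization failures.
"""


class CismrError(Exception):
    """Base class for all cismr errors."""


class SumstatsFormatError(CismrError):
    """A summary-statistics file is structurally unusable (missing columns,
    unreadable rows)."""


class ValidationError(CismrError):
    """A field value violates its contract (non-positive SE, EAF outside
    [0, 1], zero-width confidence interval, ...)."""


class HarmonizationError(CismrError):
    """Exposure and outcome alleles cannot be reconciled."""


class AmbiguousPalindromeError(HarmonizationError):
    """Palindromic (A/T or C/G) variant whose strand cannot be resolved
    because both allele frequencies are too close to 0.5."""


class ScaleError(CismrError):
    """An operation was requested on the wrong effect scale (e.g. odds-ratio
    presentation of a linear-trait result)."""
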