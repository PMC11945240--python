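"""Exception hierarchy.

Validation problems (bad counts, malformed files, inconsistent labels) raise
:class:`ValidationError`; the scientific non-result "the historical effect does
not demonstrate superiority, so no margin exists" raises
:class:`MarginUndefinedError`.  The CLI maps these to distinct exit codes so
pipelines can tell data errors from non-results.
"""


class AnchorMarginError(Exception):
    """Base class for all package errors."""


class ValidationError(AnchorMarginError, ValueError):
    """Invalid input data or configuration."""


class ZeroResponderError(ValidationError):
    """A rate-ratio SE is undefined because an arm has zero responders.

    The log-rate-ratio standard error 1/r1 + 1/r2 - 1/n1 - 1/n2 requires at
    least one responder per arm.  Pass ``continuity=True`` to apply a 0.5
    continuity correction to all four cells, or use an exact method upstream.
    """


class MarginUndefinedError(AnchorMarginError, ValueError):
    """No demonstrated effect: the CI bound does not exceed 1, so no
    equivalence margin can be derived from it."""
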