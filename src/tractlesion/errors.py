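"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`TractLesionError` so callers can catch package errors without
swallowing programming bugs.
"""


class TractLesionError(Exception):
    """Base class for all errors raised by tractlesion."""


class FormatError(TractLesionError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(TractLesionError, ValueError):
    """An input object violates a documented invariant."""


class SearchFailureError(TractLesionError):
    """An adaptive search exhausted its budget without a qualifying result.

    Carries ``trajectory``, the list of (threshold, n_clusters) pairs visited.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


class UndefinedChangeError(TractLesionError):
    """Percent change is undefined because the baseline score is zero."""
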