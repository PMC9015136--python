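"""Exception hierarchy for idpseq.

All exceptions derive from :class:`IdpseqError` so callers can catch the
package's failures with a single clause while still distinguishing
validation problems (bad user input) from capability/retrieval problems
(network access).
"""


class IdpseqError(Exception):
    """Base class for all idpseq errors."""


class ValidationError(IdpseqError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(IdpseqError, ValueError):
    """A file is not in the expected text format."""


class CapabilityError(IdpseqError, RuntimeError):
    """An optional capability (e.g. network access) is disabled."""


class RetrievalError(IdpseqError, RuntimeError):
    """A remote resource could not be retrieved."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status
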