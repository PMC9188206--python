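"""Exception hierarchy shared across the package.

Everything derives from :class:`TeadscoreError` so callers can catch the
package's failures with one clause; the subclasses distinguish malformed
files, invariant violations, per-sample scoring failures and bad call
arguments.
"""


class TeadscoreError(Exception):
    """Base class for all errors raised by teadscore."""


class FormatError(TeadscoreError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(TeadscoreError, ValueError):
    """Parsed content violates a domain invariant (duplicate ids, out-of-range values, overlapping sets)."""


class ScoringError(TeadscoreError, ValueError):
    """A sample cannot be scored (too few measured values, an effector direction with no measured members)."""


class UsageError(TeadscoreError, ValueError):
    """An operation was called with arguments outside its contract."""
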