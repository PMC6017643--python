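"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`BundleTracError` so the CLI
can map failures onto its exit-code contract (2 = validation, 3 = I/O).
"""


class BundleTracError(Exception):
    """Base class for all errors raised by bundletrac."""


class ValidationError(BundleTracError, ValueError):
    """Invalid arguments, inconsistent models, or violated preconditions."""


class FormatError(BundleTracError, IOError):
    """Malformed or truncated on-disk data (MRC header fields, CSV, CMM)."""


class DegenerateInputError(ValidationError):
    """An input on which the requested operation is mathematically undefined
    (e.g. a constant cross-section has no cross-correlation peak)."""


class RankDeficiencyError(ValidationError):
    """A local least-squares fit has fewer effective samples than coefficients."""
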