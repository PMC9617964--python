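"""Exception hierarchy for permnet.

All user-facing errors derive from :class:`PermnetError` so callers (and the
CLI) can distinguish expected failures from bugs.
"""


class PermnetError(Exception):
    """Base class for all permnet errors."""


class InvalidInputError(PermnetError, ValueError):
    """An argument violates a precondition (wrong shape, empty, out of range)."""


class DegenerateDesignError(PermnetError, ValueError):
    """A regression design is rank-deficient (e.g. constant predictor)."""


class ConfigurationError(PermnetError, ValueError):
    """A simulator configuration is internally inconsistent or produces
    invalid probabilities."""


class FormatError(PermnetError, ValueError):
    """A CSV/text input file does not conform to the documented format."""
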