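"""Exception hierarchy.

All refstab errors derive from :class:`RefstabError` so callers (and the CLI)
can distinguish validation problems (bad input, exit code 2) from estimation
failures (a method's preconditions not met by the data, exit code 3).
"""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class ValidationError(RefstabError, ValueError):
    """Input violates a declared contract (unknown factor level, duplicate
    sample, malformed weights, mismatched gene sets, ...)."""


class ParseError(ValidationError):
    """A delimited-text Cq file could not be parsed; message carries the
    offending line or column where known."""


class EmptySelectionError(ValidationError):
    """A subset request matched no samples/genes."""


class EstimationError(RefstabError, RuntimeError):
    """A stability estimator or quantification step cannot run on the given
    data (too few genes, too few shared samples, empty condition, ...)."""
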