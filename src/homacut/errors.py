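"""Exception hierarchy.

``InputError`` marks invalid user-supplied data (bad values, missing
columns, empty strata); everything else raised by the package is a plain
``HomacutError`` or a library exception propagated unchanged. The CLI maps
``InputError`` to exit code 1 and any other failure to exit code 2.
"""


class HomacutError(Exception):
    """Base class for errors raised by this package."""


class InputError(HomacutError, ValueError):
    """Invalid input data or parameters supplied by the caller."""


class EmptyStratumError(InputError):
    """A required stratum (age/sex/height band) is empty or undersized."""


class DegenerateDataError(InputError):
    """Data degenerate for the requested operation (e.g. all-tied quintiles)."""
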