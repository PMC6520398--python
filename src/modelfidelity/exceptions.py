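"""Exception hierarchy shared across the package."""


class ModelFidelityError(Exception):
    """Base class for all package errors."""


class FormatError(ModelFidelityError, ValueError):
    """A file or table violates the expected dialect or an invariant.

    The message names the offending row/column/cell wherever possible.
    """


class DomainError(ModelFidelityError, ValueError):
    """An argument lies outside its mathematical domain (e.g. q outside (0,1))."""


class DegenerateDataError(ModelFidelityError, ValueError):
    """Input is too small or too uniform for the statistic to be defined
    (constant vectors, empty groups, all-missing correlations)."""
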