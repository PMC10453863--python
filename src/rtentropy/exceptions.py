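"""Exception hierarchy.

The CLI maps these onto its exit-code contract: usage errors exit 2,
validation errors 3, numerical failures 4.
"""


class RTEntropyError(Exception):
    """Base class for all rtentropy errors."""


class ParameterError(RTEntropyError, ValueError):
    """A distribution parameter is outside its domain (sigma<=0, tau<=0, lam<=0)."""


class ValidationError(RTEntropyError, ValueError):
    """Input data violate a contract (nonpositive duration, bad survivor values...)."""


class UsageError(RTEntropyError, ValueError):
    """An operation was called incorrectly (wrong curve kind, mismatched grids...)."""


class EstimatorError(RTEntropyError, ValueError):
    """An estimator is undefined for the given input (too few points...)."""
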