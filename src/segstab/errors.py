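"""Exception hierarchy for the segstab pipeline.

Every stage raises a subclass of :class:`SegstabError`, so callers (and the
CLI) can distinguish user-input problems from numerical failures.
"""


class SegstabError(Exception):
    """Base class for all segstab errors."""


class SchemaError(SegstabError):
    """A required column or field is missing from an input table."""


class IntegrityError(SegstabError):
    """Duplicate keys or otherwise inconsistent records."""


class InputError(SegstabError):
    """A precondition on user-supplied data or configuration is violated."""


class EstimabilityError(SegstabError):
    """The segmented design matrix is rank deficient (e.g. no favorable
    environments, so the change-point regressor is identically zero)."""


class DegeneratePriorError(SegstabError):
    """Hyperparameter elicitation would produce a degenerate prior
    (e.g. zero residual variance from a noiseless fit)."""


class DegenerateChainError(SegstabError):
    """An MCMC chain has zero variance, so a diagnostic is undefined."""


class NumericalError(SegstabError):
    """A non-finite value appeared during sampling or deviance evaluation."""


class StateError(SegstabError):
    """An object is missing a component required by the requested operation."""
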