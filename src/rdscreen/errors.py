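"""Exception hierarchy for rdscreen.

All package-raised errors derive from :class:`RDScreenError`, so callers
(including the CLI) can distinguish configuration problems, bad inputs,
and estimation failures from programming errors.
"""


class RDScreenError(Exception):
    """Base class for all errors raised by rdscreen."""


class ConfigurationError(RDScreenError):
    """An analysis or simulation configuration is invalid; message names the field."""


class InputError(RDScreenError):
    """An input table or value violates a precondition (non-finite x, empty stratum...)."""


class SampleSizeError(RDScreenError):
    """Too few usable observations on one side of the cutoff for the requested fit."""


class EstimationError(RDScreenError):
    """The estimation problem is degenerate (e.g. rank-deficient design)."""


class SeparationError(EstimationError):
    """A binary outcome is constant on one side of the cutoff; the risk ratio is not identified."""


class ConvergenceError(EstimationError):
    """Iterative estimation failed to converge within the iteration cap."""


class SelectionError(RDScreenError):
    """Data-driven bandwidth selection failed (degenerate variance or density)."""
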