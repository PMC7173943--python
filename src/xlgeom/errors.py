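"""Exception hierarchy shared across the pipeline."""


class XlgeomError(Exception):
    """Base class for all package errors."""


class FormatError(XlgeomError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(XlgeomError):
    """An input that must be non-empty (structure, table) was empty."""


class ResidueLookupError(XlgeomError, KeyError):
    """A residue id could not be resolved in a structure."""


class IncompleteResidueError(XlgeomError):
    """A residue lacks the atoms required for the requested operation."""


class InsufficientEnsembleError(XlgeomError):
    """Too few ensemble members carry the requested residue."""


class UnderdeterminedError(XlgeomError):
    """Too few matched atoms to determine a superposition."""


class FitFailureError(XlgeomError):
    """A nonlinear fit failed to converge; the message carries diagnostics."""


class SamplingFailureError(XlgeomError):
    """No finite-energy starting pose could be generated."""
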