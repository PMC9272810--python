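"""Exception hierarchy shared by all mirta modules."""


class MirtaError(Exception):
    """Base class for all errors raised by mirta."""


class FormatError(MirtaError):
    """An input file does not conform to its expected text format."""


class ValidationError(MirtaError):
    """A constructed object or parameter violates a documented invariant."""


class SampleOverlapError(MirtaError):
    """Too few samples are shared between inputs for a paired analysis."""


class AnalysisError(MirtaError):
    """An analysis precondition fails (degenerate input, empty selection...)."""
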