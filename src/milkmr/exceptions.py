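"""Exception hierarchy shared by all pipeline stages."""


class MilkMRError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MilkMRError, ValueError):
    """Invalid inputs: out-of-range parameters, malformed tables, bad codes."""


class AnalysisError(MilkMRError, RuntimeError):
    """A statistical stage cannot produce a result (e.g. zero cases)."""


class HarmonizationError(ValidationError):
    """Summary statistics cannot be aligned to a common effect allele."""
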