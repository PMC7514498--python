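"""Exception hierarchy for speechlaws."""


class SpeechLawsError(Exception):
    """Base class for all speechlaws errors."""


class ParseError(SpeechLawsError):
    """An annotation file could not be parsed (names the offending line/tier)."""


class ValidationError(SpeechLawsError):
    """A corpus hierarchy violates a structural invariant."""


class FitError(SpeechLawsError):
    """An estimator could not produce a fit (degenerate data or non-convergence)."""


class DegenerateSampleError(FitError):
    """The sample has no usable variation (constant values, no tail, ...)."""
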