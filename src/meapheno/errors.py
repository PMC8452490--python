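"""Exception types shared across the pipeline."""


class MeaPhenoError(Exception):
    """Base class for all package errors."""


class FormatError(MeaPhenoError):
    """A file could not be parsed under the named dialect."""


class ValidationError(MeaPhenoError, ValueError):
    """Input data violates a structural invariant (e.g. unsorted timestamps)."""


class ParameterError(MeaPhenoError, ValueError):
    """A setting is outside its admissible range (e.g. cutoff above Nyquist)."""


class AnalysisError(MeaPhenoError):
    """An analysis step cannot proceed on this input (e.g. no network bursts)."""
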