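"""Exception hierarchy shared across the analysis stages."""


class FixsearchError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(FixsearchError):
    """Too few observations (fixations, spikes, stimuli, segments) for a stage."""


class DegenerateInputError(FixsearchError):
    """Input with no usable variance (constant rates, zero vectors, rank loss)."""


class SameElectrodeError(FixsearchError):
    """Spike unit and LFP channel share an electrode; coherence would be biased."""


class UnstableModelError(FixsearchError):
    """Fitted VAR model is not stable (companion spectral radius >= 1)."""


class SessionIOError(FixsearchError):
    """A session directory is missing or has a corrupt component file."""
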