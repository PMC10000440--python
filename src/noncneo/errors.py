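"""Exception hierarchy for the noncneo pipeline."""


class NoncneoError(Exception):
    """Base class for all pipeline errors."""


class VcfFormatError(NoncneoError):
    """The VCF input is malformed or missing required columns."""


class AnnotationFormatError(NoncneoError):
    """The annotation table is missing a required column."""


class ReferenceMismatchError(NoncneoError):
    """A variant's REF allele disagrees with the reference genome."""


class ContigNotFoundError(NoncneoError):
    """A variant names a contig absent from the reference genome."""


class AlphabetError(NoncneoError):
    """A sequence contains characters outside the expected alphabet."""


class PredictorError(NoncneoError):
    """A binding predictor is unavailable or misconfigured."""


class ConfigurationError(NoncneoError):
    """A screen or evaluation was configured with unusable inputs."""
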