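"""Exception hierarchy shared across the pipeline."""


class PvarchError(Exception):
    """Base class for all package errors."""


class FormatError(PvarchError):
    """A file does not conform to its documented schema."""


class ValidationError(PvarchError):
    """Input parsed but violates a semantic invariant."""


class NotASNVError(ValidationError):
    """Allele pair is not a single-nucleotide substitution."""


class ConfigurationError(PvarchError):
    """A pipeline or simulation configuration is incomplete or inconsistent."""


class AnalysisError(PvarchError):
    """An analysis cannot proceed on the given data (e.g. too few groups)."""
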