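"""Exception hierarchy for the pipeline."""


class ToxconcordError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigurationError(ToxconcordError):
    """A study design / generator configuration violates its invariants."""


class InvalidInputError(ToxconcordError):
    """An input table or argument is inconsistent (negative LDH, bad counts...)."""


class InsufficientSamplesError(ToxconcordError):
    """A stratum has too few samples for the QC statistics."""


class MissingControlError(ToxconcordError):
    """A treated group has no matched solvent control in the metadata."""


class NormalizationError(ToxconcordError):
    """Median-of-ratios normalization cannot proceed.

    Raised when no probe has all-positive counts; callers may retry with
    ``fallback_total_count=True`` to scale by total counts instead.
    """
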