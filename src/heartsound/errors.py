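"""Typed exceptions used across the pipeline.

Unsegmentable or unreadable recordings are expected events in field data
(a sizeable fraction of phone auscultations is uninterpretable), so they
raise dedicated types that the pipeline catches and records per recording
instead of crashing.
"""


class HeartSoundError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeartSoundError, ValueError):
    """A parameter or config field is invalid; the message names the field."""


class SegmentationFailure(HeartSoundError):
    """Too few detectable heart-sound events to partition into cycles."""


class FeatureExtractionError(HeartSoundError):
    """A cardiac cycle could not be converted into a spectrogram feature."""


class FormatError(HeartSoundError):
    """An input file is missing, unreadable, or in an unsupported encoding."""
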