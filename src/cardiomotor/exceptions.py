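"""Exception hierarchy used across the package."""


class CardioMotorError(Exception):
    """Base class for all package errors."""


class FormatError(CardioMotorError):
    """A file could not be parsed as the declared format."""


class ParameterError(CardioMotorError):
    """An argument violates a precondition (e.g. band edge above Nyquist)."""


class ChannelError(CardioMotorError):
    """A required channel is missing or has the wrong role."""


class EmptyEpochsError(CardioMotorError):
    """No usable events survived epoching."""


class DetectionError(CardioMotorError):
    """A signal-detection step (R-peaks, onsets) found nothing usable."""


class ConfigError(CardioMotorError):
    """A synthesis or study configuration is internally inconsistent."""


class StageError(CardioMotorError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
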