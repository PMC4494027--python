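"""Exception hierarchy."""


class BlockMvpaError(Exception):
    """Base class for all package errors."""


class ConfigError(BlockMvpaError):
    """Invalid configuration or design parameters."""


class EventTableError(BlockMvpaError):
    """Malformed or inconsistent event table."""


class VolumeIOError(BlockMvpaError):
    """Volumetric file could not be read or written."""


class DesignMatrixError(BlockMvpaError):
    """Design matrix construction or rank problem."""


class RoiError(BlockMvpaError):
    """ROI growth or summary failure (e.g. mask smaller than request)."""


class PatternError(BlockMvpaError):
    """Pattern-preparation contract violation."""


class DecodingError(BlockMvpaError):
    """Cross-validation setup problem."""


class StatsError(BlockMvpaError):
    """Group-statistics input problem."""


class PipelineStageError(BlockMvpaError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
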