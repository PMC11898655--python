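"""Exception types shared across the pipeline."""


class PoleprofError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PoleprofError):
    """A parameter set or config file is incomplete or inconsistent."""


class CellFlagged(PoleprofError):
    """A single cell was excluded from analysis; ``reason`` says why."""

    def __init__(self, cell_id, reason: str):
        self.cell_id = cell_id
        self.reason = reason
        super().__init__(f"cell {cell_id} excluded: {reason}")


class CalibrationError(PoleprofError):
    """Prominence calibration could not reach a usable agreement level."""


class PipelineError(PoleprofError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
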