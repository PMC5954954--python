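"""Exception hierarchy shared across the pipeline."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetpharmError, ValueError):
    """An input file violates the format it declares (bad column, bad score scale, short line)."""


class UsageError(NetpharmError, ValueError):
    """A function was called with arguments outside its contract."""


class PipelineError(NetpharmError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
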