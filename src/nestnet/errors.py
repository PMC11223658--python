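"""Exception hierarchy for nestnet."""


class NestnetError(Exception):
    """Base class for all nestnet errors."""


class FormatError(NestnetError):
    """A table or file failed structural validation."""


class InvalidConfigError(NestnetError):
    """A configuration value is outside its allowed domain."""


class PipelineError(NestnetError):
    """A pipeline stage failed; the stage name is carried in ``stage``."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
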