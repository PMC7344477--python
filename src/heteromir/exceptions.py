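"""Exception hierarchy shared across the package."""


class HeteromirError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeteromirError):
    """A delimited-text input violates the expected layout or content."""


class VocabularyError(FormatError):
    """A label falls outside a closed controlled vocabulary (e.g. regions)."""


class InsufficientDataError(HeteromirError):
    """Too few complete observations to compute the requested statistic."""


class ConfigError(HeteromirError):
    """A configuration object is internally inconsistent."""


class PipelineError(HeteromirError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
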