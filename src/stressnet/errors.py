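"""Exception hierarchy for the stressnet pipeline."""


class StressnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(StressnetError):
    """Invalid configuration (bad parameter values, malformed config files)."""


class DataError(StressnetError):
    """Invalid or malformed data (parse failures, contract violations)."""


class StageError(StressnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class NoMoveError(StressnetError):
    """The structure-search proposer found no valid local move."""
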