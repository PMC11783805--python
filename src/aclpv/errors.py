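"""Exception hierarchy for the aclpv package."""


class AclpvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AclpvError, ValueError):
    """Raised when an input table, record or value violates its contract."""


class ConfigurationError(AclpvError, ValueError):
    """Raised when a run or covariate configuration cannot be resolved."""


class StageError(AclpvError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage={stage}] {message}")
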