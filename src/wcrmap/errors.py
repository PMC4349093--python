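"""Exception hierarchy shared across the package."""


class WcrmapError(Exception):
    """Base class for all package-specific errors."""


class DataError(WcrmapError):
    """Malformed or contract-violating input data (files or in-memory)."""


class ExtinctionError(WcrmapError):
    """A simulated F2 arm produced zero survivors."""

    def __init__(self, arm: str, message: str | None = None):
        self.arm = arm
        super().__init__(message or f"no survivors in the {arm} arm")


class ConditioningError(WcrmapError):
    """Conditioning rule produced an empty subset; carries diagnostic counts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
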