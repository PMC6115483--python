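"""Exception types shared across the package."""


class ShiftSimError(Exception):
    """Base class for all shiftsim errors."""


class InvalidParameterError(ShiftSimError, ValueError):
    """A parameter violates an operation's preconditions."""


class InfeasibleLoadError(ShiftSimError, ValueError):
    """The requested load exceeds the muscle's maximum strength."""


class BisectionError(ShiftSimError, RuntimeError):
    """Root bracketing / bisection failed to converge.

    Carries the last bracket as ``(lo, hi)`` in force units.
    """

    def __init__(self, message: str, bracket: tuple[float, float]):
        super().__init__(message)
        self.bracket = bracket


class ConfigError(ShiftSimError, ValueError):
    """A run configuration field failed validation.

    ``field`` names the offending configuration entry.
    """

    def __init__(self, field: str, message: str):
        super().__init__(f"invalid config field {field!r}: {message}")
        self.field = field
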