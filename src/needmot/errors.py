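"""Exception hierarchy shared across the package."""


class NeedmotError(Exception):
    """Base class for all package-specific errors."""


class ScheduleError(NeedmotError, ValueError):
    """An event schedule violates its ordering/window invariants."""


class ParameterShapeError(NeedmotError, ValueError):
    """Model parameters do not match the schedule (e.g. wrong number of steps)."""


class AlignmentError(NeedmotError, ValueError):
    """Traces disagree in rate, window, or length where they must match."""


class WindowError(NeedmotError, ValueError):
    """A requested analysis window is incompatible with the data."""


class FitError(NeedmotError, RuntimeError):
    """Optimization failed across all restarts."""


class ConfigError(NeedmotError, ValueError):
    """A run configuration file is invalid."""
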