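"""Exception and warning types for autoxkin."""


class AutoxkinError(Exception):
    """Base class for all autoxkin errors."""


class AutoxkinWarning(UserWarning):
    """Base class for all autoxkin warnings."""


class IntegrationFailure(AutoxkinError):
    """The ODE integrator produced a non-finite or negative state.

    The message names the first offending species.
    """


class OracleUndefinedError(AutoxkinError):
    """A closed-form steady-state oracle is undefined (e.g. 2k_t = 0)."""


class NoBreakpointError(AutoxkinError):
    """No induction-period breakpoint could be detected in a trace."""


class InsufficientDataError(AutoxkinError):
    """A fit window contains too few points."""


class FitFailureError(AutoxkinError):
    """A regression produced a non-physical result (e.g. non-positive slope)."""


class GenerationError(AutoxkinError):
    """Synthetic-trace generation failed (e.g. injection point never reached)."""


class TraceFormatError(AutoxkinError):
    """A trace file violates the on-disk format contract."""


class MissingReferenceError(AutoxkinError):
    """A required reference (uninhibited or calibration) trace is missing."""
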