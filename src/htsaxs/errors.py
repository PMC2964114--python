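"""Exception hierarchy for the acquisition framework."""


class BeamlineError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(BeamlineError):
    """An input violates a documented range, capacity or format contract."""


class PlanError(ValidationError):
    """A screening plan (or plan spreadsheet) is invalid.

    Carries the full list of violations so a user can fix a spreadsheet in
    one pass instead of replaying import once per error.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ArbitrationError(BeamlineError):
    """A client tried something its session role does not permit."""


class DeviceFault(BeamlineError):
    """A simulated device failed to complete a commanded action."""


class IllegalTransition(BeamlineError):
    """An operation status was asked to make a transition the state machine forbids."""
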