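"""Exception hierarchy for coordlearn."""


class CoordlearnError(Exception):
    """Base class for all coordlearn errors."""


class InvalidParameterError(CoordlearnError, ValueError):
    """A parameter failed validation (non-finite, out of range, wrong shape)."""


class DegenerateTrialError(CoordlearnError, ValueError):
    """A trial is unusable for phase estimation (e.g. near-zero amplitude)."""


class UndefinedPhaseError(CoordlearnError, ValueError):
    """Phase is undefined at a sample (position and velocity both zero)."""


class DegenerateVarianceError(CoordlearnError, ValueError):
    """A test statistic is undefined because the contrast variance is zero."""


class FitFailureError(CoordlearnError, RuntimeError):
    """Nonlinear fit did not converge; carries diagnostics in args."""


class ParseError(CoordlearnError, ValueError):
    """An on-disk trial file or manifest failed validation."""


class ProtocolError(CoordlearnError, ValueError):
    """A training-protocol update was invalid (wrong trial count, already stopped)."""


class StaircaseError(CoordlearnError, ValueError):
    """A staircase operation was invalid (update after finish, too few reversals)."""
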