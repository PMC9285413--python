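"""Exception hierarchy for gravicor."""


class GravicorError(Exception):
    """Base class for all package errors."""


class ParameterError(GravicorError):
    """A physical parameter is out of its admissible range or non-finite."""


class ConfigError(GravicorError):
    """A configuration file or network description is inconsistent."""


class IntegrationError(GravicorError):
    """The ODE integrator failed."""


class ConvergenceError(GravicorError):
    """Periodic steady state or a fixed-point loop did not converge."""

    def __init__(self, message, residuals=None, history=None):
        super().__init__(message)
        self.residuals = residuals
        self.history = history


class CalibrationError(ConvergenceError):
    """Baseline calibration failed to meet its targets."""


class AnalysisError(GravicorError):
    """A beat-level quantity (e.g. end-systole) could not be identified."""
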