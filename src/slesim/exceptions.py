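"""Exception hierarchy for slesim."""


class SlesimError(Exception):
    """Base class for all slesim errors."""


class ConfigurationError(SlesimError):
    """Invalid configuration value or schema violation."""


class TopologyError(SlesimError):
    """Inconsistent network topology (degrees, distances, groups)."""


class NumericalError(SlesimError):
    """Non-finite state encountered during integration.

    Carries the neuron index and simulation time at which the
    failure was detected.
    """

    def __init__(self, message, neuron=None, time_ms=None):
        super().__init__(message)
        self.neuron = neuron
        self.time_ms = time_ms


class CalibrationError(SlesimError):
    """Transmission-ratio calibration failed to converge.

    ``achieved_ratio`` holds the best (syn, field) percentage shares
    reached before giving up.
    """

    def __init__(self, message, achieved_ratio=None, params=None):
        super().__init__(message)
        self.achieved_ratio = achieved_ratio
        self.params = params


class AnalysisError(SlesimError):
    """Signal-analysis precondition violated."""


class InsufficientDataError(AnalysisError):
    """Too few events (e.g. matched peaks) to compute a statistic."""
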