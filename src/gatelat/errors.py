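"""Exception hierarchy for the gating-latency pipeline.

Every stage raises a subclass of :class:`GatelatError` so callers (and the
CLI) can distinguish analysis failures from programming errors.
"""


class GatelatError(Exception):
    """Base class for all gatelat-specific failures."""


class ConfigurationError(GatelatError):
    """A parameter value is invalid; the message names the offending field."""


class InfeasibleScenarioError(GatelatError):
    """A simulation scenario cannot produce physically consistent signals
    (e.g. the gate interval is shorter than the signal rise times)."""


class NoCyclesError(GatelatError):
    """No motion peak region was found (flat or degenerate motion channel)."""


class InsufficientCyclesError(GatelatError):
    """Fewer than two interior motion peaks: no complete cycle to analyze."""


class DegeneratePeakError(GatelatError):
    """A fitted peak lies on the boundary of its region instead of inside it."""


class FitError(GatelatError):
    """The polynomial peak fit is underdetermined."""


class NoEdgesError(GatelatError):
    """A logic channel contains no excursion above its high threshold."""


class LowSNRError(GatelatError):
    """A channel's dynamic range is below the configured noise floor."""


class AmbiguityError(GatelatError):
    """Event-to-cycle association is ambiguous (overlapping candidate windows)."""


class InsufficientDataError(GatelatError):
    """Too few complete cycles to compute the requested statistics."""


class RecordingParseError(GatelatError):
    """A recording file is malformed (header, NaN sample, non-uniform time)."""


class PipelineError(GatelatError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
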