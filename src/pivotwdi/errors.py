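"""Exception hierarchy for pivotwdi."""


class PivotWdiError(Exception):
    """Base class for all package errors."""


class ValidationError(PivotWdiError):
    """An input violated a documented invariant (range, finiteness, shape)."""


class DegenerateTrapezoidError(PivotWdiError):
    """Upper temperature limit did not exceed the lower limit for a timestep."""


class MissingWeatherError(PivotWdiError):
    """Weather series does not cover a requested timestamp or has gaps."""
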