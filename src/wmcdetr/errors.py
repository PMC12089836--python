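"""Exception types shared across the package."""


class ArgumentError(ValueError):
    """A caller-supplied argument violates an operation's preconditions."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent or unsupported."""


class ParseError(ValueError):
    """An annotation file could not be parsed; the message names the spot."""


class ProfilingError(RuntimeError):
    """The analytic profiler met a layer it has no cost model for."""


class NumericalError(RuntimeError):
    """Non-finite values surfaced inside a layer; the message names it."""
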