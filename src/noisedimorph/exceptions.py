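"""Exception hierarchy used across the package."""


class NoiseDimorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NoiseDimorphError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InsufficientReplicationError(NoiseDimorphError, ValueError):
    """Fewer than two replicate values were supplied where a CV is required."""


class DegenerateMeanError(NoiseDimorphError, ValueError):
    """The mean of the replicate values is non-positive, so CV is undefined."""


class DegenerateFitError(NoiseDimorphError, ValueError):
    """The regression design matrix is rank deficient (e.g. constant x)."""


class ParseError(NoiseDimorphError, ValueError):
    """A genomic-interval or tabular input file is malformed."""


class FixtureError(NoiseDimorphError, RuntimeError):
    """The packaged data fixture is missing or corrupted."""
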