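"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so scripted callers can tell a
malformed configuration from malformed data from a numerical failure.
"""


class MRPipeError(Exception):
    """Base class for all package errors."""


class ConfigError(MRPipeError):
    """Invalid user configuration (thresholds, bootstrap sizes, policies...)."""


class SchemaError(MRPipeError):
    """A summary-statistics file is structurally unusable (missing columns)."""


class HarmonizationError(MRPipeError):
    """Exposure and outcome tables cannot be aligned (e.g. no shared SNPs)."""


class InstrumentError(MRPipeError):
    """Instrument selection left too few (or invalid) instruments."""


class EstimationError(MRPipeError):
    """An estimator's preconditions are not met (n_snp too small, null bx...)."""
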