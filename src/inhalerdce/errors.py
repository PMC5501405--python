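"""Exception types shared across the package."""


class SchemaError(ValueError):
    """An attribute schema violates its invariants."""


class ConfigError(ValueError):
    """A run/cohort/MCMC configuration is inconsistent."""


class DataError(ValueError):
    """Input choice/ranking data violates the long-format contract."""


class EstimationError(RuntimeError):
    """A fit is too degenerate to report the requested quantity."""
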