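"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or run configuration violates its invariants."""


class EstimationError(RuntimeError):
    """A model fit could not be carried out (rank deficiency, too few rows,
    non-convergence)."""
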