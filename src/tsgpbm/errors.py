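"""Exception hierarchy shared across the package."""


class GridMismatchError(ValueError):
    """Two objects that must live on the same size grid do not."""


class DegenerateInputError(ValueError):
    """An input carries no information (e.g. an all-zero PSD)."""


class FormatError(ValueError):
    """A PSD table or configuration file violates the expected layout."""


class SolverError(RuntimeError):
    """Time integration failed or violated a conservation tolerance."""


class ConfigError(ValueError):
    """A run configuration failed validation; message lists all violations."""
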