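"""Exception hierarchy shared across the pipeline."""


class CnvarError(Exception):
    """Base class for all package errors."""


class InputError(CnvarError):
    """Malformed or unusable input data (tables, annotation files)."""


class ConfigurationError(CnvarError):
    """Inconsistent user configuration (unknown condition, missing sample...)."""


class ModelError(CnvarError):
    """A compartment model cannot be fitted (too few points, degenerate x)."""
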