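"""Exception hierarchy shared across the pipeline."""


class SigrespError(Exception):
    """Base class for all package errors."""


class ConfigError(SigrespError, ValueError):
    """Invalid generator or pipeline configuration."""


class DesignError(SigrespError, ValueError):
    """Sample design violates the requirements of an operation."""


class SchemaError(SigrespError, ValueError):
    """A tab-delimited artifact does not match its expected schema."""


class AssayError(SigrespError, ValueError):
    """Phenotype assay input fails validation."""
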