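"""Exception hierarchy for the perturbmap pipeline."""


class PerturbmapError(Exception):
    """Base class for all package errors."""


class FormatError(PerturbmapError):
    """A data file is missing, malformed, or inconsistent with its companions."""


class ConfigurationError(PerturbmapError):
    """A configuration value or a design/data mismatch prevents the operation."""


class EmptyResultError(PerturbmapError):
    """A filtering operation removed everything."""


class InferenceError(PerturbmapError):
    """Numerical failure during model fitting (e.g. non-finite ELBO)."""
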