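"""Exception hierarchy shared across the pipeline stages."""


class ClusterNetError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ClusterNetError):
    """A file could not be parsed into the expected on-disk format."""


class EmptyInputError(ClusterNetError):
    """An input table or graph contained no usable rows/nodes."""


class EmptyResultError(ClusterNetError):
    """A filtering or clustering step removed everything."""


class DegenerateSampleError(ClusterNetError):
    """A sampler or geometric computation produced a degenerate result
    (e.g. an ROI with zero localizations, or an all-identical point set)."""


class PreconditionError(ClusterNetError):
    """An operation was called on input violating its contract."""


class ConfigError(ClusterNetError):
    """Invalid configuration (unknown keys, inconsistent dimensions...)."""
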