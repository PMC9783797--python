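"""Exception hierarchy.

All library errors derive from :class:`EcoqiError` so callers (and the CLI)
can distinguish contract violations from genuine bugs.
"""


class EcoqiError(Exception):
    """Base class for all ecoqi errors."""


class GridAlignmentError(EcoqiError):
    """Two rasters that must share a grid do not."""


class RasterIOError(EcoqiError):
    """Reading or writing a raster file failed."""


class ContractError(EcoqiError):
    """An operation was called outside its preconditions."""


class ConfigurationError(EcoqiError):
    """Unknown sensor tag, bad config key, or invalid parameter."""


class FittingError(EcoqiError):
    """Normalization or PCA fitting is impossible on the given data."""


class DegenerateModelError(FittingError):
    """PCA on rank-0 data (all sampled cells identical)."""
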