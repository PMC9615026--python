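"""Exception hierarchy shared across the pipeline."""


class PunctaError(Exception):
    """Base class for all errors raised by this package."""


class StackError(PunctaError):
    """Malformed or unreadable image stack, or invalid channel roles."""


class GeometryError(PunctaError):
    """Invalid cell outline, center, ROI, or shell construction."""


class SegmentationError(PunctaError):
    """Segmentation preconditions violated (missing channel, bad method string)."""


class EnrichmentError(PunctaError):
    """Enrichment undefined for this cell (empty analysis mask, no cytosol,
    zero construct intensity). Pipelines treat this as a per-cell exclusion."""


class StatsError(PunctaError):
    """Statistical routine called with insufficient or invalid data."""


class ConfigError(PunctaError):
    """Pipeline configuration failed validation."""
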