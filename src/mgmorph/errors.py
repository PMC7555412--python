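"""Exception hierarchy shared by all pipeline stages."""


class MgmorphError(Exception):
    """Base class for all mgmorph errors."""


class ConfigurationError(MgmorphError, ValueError):
    """A configuration value violates an invariant (names the field)."""


class SchemaError(MgmorphError, ValueError):
    """A table does not conform to its declared schema."""


class ImageFormatError(MgmorphError, ValueError):
    """An image file has an unsupported layout (e.g. channel count)."""


class CapacityError(MgmorphError, RuntimeError):
    """Synthetic objects cannot be placed without overlap in the frame."""


class SamplingError(MgmorphError, ValueError):
    """A class is too small for the requested sample size."""


class MetadataError(MgmorphError, KeyError):
    """A slide or image lacks required metadata (e.g. genotype)."""


class AnnotationError(MgmorphError, ValueError):
    """A slide annotation is inconsistent (e.g. positive quadrant off-grid)."""


class DegenerateInputError(MgmorphError, ValueError):
    """Input is structurally valid but degenerate (empty white matter, zero extent)."""


class LabelingError(MgmorphError, RuntimeError):
    """Cluster-to-state labeling is ambiguous and needs a manual override."""


class ManifestError(MgmorphError, ValueError):
    """A run manifest is invalid or references missing inputs."""
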