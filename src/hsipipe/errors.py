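"""Exception hierarchy for the pipeline."""


class HsiPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(HsiPipeError):
    """Invalid design, scene, selector or grid configuration."""


class ReferenceFrameError(HsiPipeError):
    """Dark/white reference frames unusable for radiometric correction."""


class SegmentationError(HsiPipeError):
    """Leaf segmentation produced an empty or degenerate mask."""


class EmptySelectionError(HsiPipeError):
    """A wavelength selector eliminated every band."""


class MeasurementError(HsiPipeError):
    """Physically impossible assay reading (e.g. conductivities C1 > C2)."""


class DegenerateDataError(HsiPipeError):
    """Zero-variance target, rank collapse, or similarly degenerate input."""
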