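"""Exception hierarchy for the airway labeling pipeline."""


class AirwayLobesError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(AirwayLobesError):
    """The input file could not be read as a supported volume format."""


class EmptyMaskError(AirwayLobesError):
    """A binary mask contains no object voxels."""


class ClassificationError(AirwayLobesError):
    """The anatomical rules cannot be applied (e.g. trachea has <2 children)."""


class PhantomSpecError(AirwayLobesError):
    """A phantom specification is geometrically invalid."""
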