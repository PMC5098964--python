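"""Exception hierarchy for the package."""


class ElefootError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ElefootError):
    """A pressure-record file is malformed (bad header, bad frame, negative pressure)."""


class SchemaError(ElefootError):
    """A delimited table is missing required columns."""


class GeometryError(ElefootError):
    """A placement or coordinate falls outside the plate or an image grid."""


class ConsistencyError(ElefootError):
    """Two objects that must belong together (step vs. record) do not."""


class SelectionError(ElefootError):
    """No candidate satisfies a selection rule (e.g. no complete template image)."""


class RegistrationError(ElefootError):
    """Automatic registration failed (non-overlapping supports)."""


class DigitizationError(ElefootError):
    """Automatic ROI digitization could not find the expected landmarks."""


class DegenerateShapeError(ElefootError):
    """A point configuration has zero centroid size and cannot be superimposed."""
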