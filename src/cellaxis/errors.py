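"""Exception hierarchy shared by all cellaxis modules.

Every domain failure raises a subclass of :class:`CellaxisError`, so callers
(and the CLI) can distinguish user/data problems from programming errors.
"""


class CellaxisError(Exception):
    """Base class for all cellaxis domain errors."""


class DuplicateCell(CellaxisError):
    """Two meshes share the same (cell_id, frame_id)."""


class ConventionMismatch(CellaxisError):
    """Inputs declare different pixel coordinate conventions."""


class CorruptDataset(CellaxisError):
    """A saved dataset directory is incomplete or fails its checksums."""


class SchemaError(CellaxisError):
    """A required column (or variable) is missing from an input file."""


class ParseError(CellaxisError):
    """A value in an input file could not be parsed (carries the row number)."""


class DegenerateGeometry(CellaxisError):
    """A polygon is collinear, self-intersecting, or has no area."""


class EmptyCell(CellaxisError):
    """No pixel centers fall inside a cell outline."""


class MissingFrame(CellaxisError):
    """A track references an image frame that the stack does not contain."""


class GroupingError(CellaxisError):
    """Invalid length-group request (e.g. more groups than cells)."""


class LineageError(CellaxisError):
    """Parent/daughter references do not form a forest."""


class DissimilarityError(CellaxisError):
    """A profile row cannot enter the requested dissimilarity (e.g. zero variance)."""


class ClusterError(CellaxisError):
    """Invalid clustering request (e.g. k larger than the number of cells)."""


class SpecError(CellaxisError):
    """A plot specification asks for an unknown kind or lacks required data."""


class DialectError(CellaxisError):
    """An unsupported fixture/importer dialect was requested."""


class GeometryError(CellaxisError):
    """Invalid shape parameters for synthetic mesh construction."""
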