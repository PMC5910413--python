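"""Exception hierarchy for the craniocurve pipeline."""


class CranioCurveError(Exception):
    """Base class for all pipeline errors."""


class MeshFormatError(CranioCurveError):
    """Input mesh file could not be parsed."""


class DegenerateMeshError(CranioCurveError):
    """Mesh is too small or degenerate after cleaning."""


class LandmarkSchemaError(CranioCurveError):
    """Landmark file is missing required keys or malformed."""


class LandmarkPlacementError(CranioCurveError):
    """A landmark lies too far from the mesh surface."""


class SegmentationError(CranioCurveError):
    """A region-of-interest selection came back empty or invalid."""


class InputError(CranioCurveError):
    """Invalid tabular or configuration input."""


class StatisticsError(CranioCurveError):
    """A statistical computation has too few usable subjects."""


class DegenerateClusteringError(CranioCurveError):
    """Clustering input admits no meaningful 2-way partition."""
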