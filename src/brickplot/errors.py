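"""Exception hierarchy for the brickplot pipeline.

Every stage raises a subclass of :class:`BrickPlotError`, so callers (and the
CLI) can catch one type and report the failing stage by exception class.
"""


class BrickPlotError(Exception):
    """Base class for all brickplot errors."""


class TableFormatError(BrickPlotError):
    """Malformed input table: duplicate labels, non-numeric cells, bad shape."""


class DimensionError(BrickPlotError):
    """Table too small for correlation/PCA (fewer than 3 markers or clusters)."""


class TransformStateError(BrickPlotError):
    """Operation applied to a table in the wrong transform state."""


class AlignmentError(BrickPlotError):
    """Marker order/count mismatch between two pipeline objects."""


class LayoutError(BrickPlotError):
    """Degenerate correlation structure; marker layout undefined."""


class ScaleError(BrickPlotError):
    """No positive expression anywhere: brick area scale undefined."""


class OverlapResolutionError(BrickPlotError):
    """Overlap resolution exhausted its search budget (canvas too crowded)."""


class ClusterLookupError(BrickPlotError, KeyError):
    """Requested cluster id absent from the table."""
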