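"""Data model for cluster-by-marker expression tables.

A brick plot is built from a single table: rows are cell clusters (from any
upstream clustering tool), columns are markers, and each cell holds the median
expression of that marker over the cluster's events.  Raw mass-cytometry ion
counts are arcsinh-transformed, ``asinh(x / cofactor)``, before any analysis:
the transform is log-like for large counts but linear near zero, and the
cofactor (conventionally 5 for CyTOF) sets where that linear range ends.
After transformation, values below a user-set cutoff (default 1.0, an
empirical background ceiling) are zeroed so that background noise produces no
brick.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, TableFormatError, TransformStateError

__all__ = [
    "TransformState",
    "ThresholdConfig",
    "ClusterExpressionTable",
    "EventMatrix",
    "read_cluster_table",
    "write_cluster_table",
    "median_by_cluster",
    "arcsinh_transform",
    "apply_zero_threshold",
]

#: Minimum marker/cluster count for correlation + PCA to be meaningful.
MIN_MARKERS = 3
MIN_CLUSTERS = 3


class TransformState(str, enum.Enum):
    RAW_COUNTS = "raw_counts"
    ARCSINH = "arcsinh"


@dataclass(frozen=True)
class ThresholdConfig:
    """Preprocessing knobs: arcsinh cofactor and the zeroing cutoff.

    ``zero_cutoff`` is on the arcsinh scale; values *strictly below* it are
    zeroed (a value exactly at the cutoff survives).  ``cofactor`` is in ion
    counts.
    """

    zero_cutoff: float = 1.0
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if not self.zero_cutoff >= 0:
            raise ValueError(f"zero_cutoff must be >= 0, got {self.zero_cutoff}")
        if not self.cofactor > 0:
            raise ValueError(f"cofactor must be > 0, got {self.cofactor}")


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TableFormatError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class ClusterExpressionTable:
    """Clusters x markers matrix of median expression values.

    ``values[i, j]`` is the expression of marker ``marker_names[j]`` in
    cluster ``cluster_ids[i]``.  ``transform_state`` records whether values
    are raw ion counts or already arcsinh-transformed; the cofactor is kept
    once the transform has been applied.
    """

    marker_names: tuple[str, ...]
    cluster_ids: tuple[str, ...]
    values: np.ndarray
    transform_state: TransformState = TransformState.RAW_COUNTS
    cofactor: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "marker_names", tuple(str(m) for m in self.marker_names))
        object.__setattr__(self, "cluster_ids", tuple(str(c) for c in self.cluster_ids))
        object.__setattr__(self, "transform_state", TransformState(self.transform_state))
        if vals.ndim != 2:
            raise TableFormatError(f"values must be 2-D, got shape {vals.shape}")
        n_clusters, n_markers = vals.shape
        if n_clusters != len(self.cluster_ids):
            raise TableFormatError(
                f"{len(self.cluster_ids)} cluster ids but {n_clusters} rows"
            )
        if n_markers != len(self.marker_names):
            raise TableFormatError(
                f"{len(self.marker_names)} marker names but {n_markers} columns"
            )
        _check_unique(self.marker_names, "marker")
        _check_unique(self.cluster_ids, "cluster")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise TableFormatError(
                f"non-finite value at cluster {self.cluster_ids[i]!r}, "
                f"marker {self.marker_names[j]!r}"
            )
        if self.transform_state is TransformState.RAW_COUNTS and np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative raw count at cluster {self.cluster_ids[i]!r}, "
                f"marker {self.marker_names[j]!r}"
            )

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def cluster_row(self, cluster_id: str) -> np.ndarray:
        from .errors import ClusterLookupError

        try:
            i = self.cluster_ids.index(str(cluster_id))
        except ValueError:
            raise ClusterLookupError(
                f"unknown cluster id {cluster_id!r}; available: "
                f"{list(self.cluster_ids)}"
            ) from None
        return self.values[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values),
            index=pd.Index(self.cluster_ids, name="cluster"),
            columns=list(self.marker_names),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        transform_state: TransformState = TransformState.RAW_COUNTS,
        cofactor: float | None = None,
    ) -> "ClusterExpressionTable":
        return cls(
            marker_names=tuple(str(c) for c in df.columns),
            cluster_ids=tuple(str(i) for i in df.index),
            values=df.to_numpy(dtype=float),
            transform_state=transform_state,
            cofactor=cofactor,
        )


@dataclass(frozen=True)
class EventMatrix:
    """Per-event expression (events x markers) with a cluster label per event."""

    marker_names: tuple[str, ...]
    events: np.ndarray
    cluster_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        ev.setflags(write=False)
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "marker_names", tuple(str(m) for m in self.marker_names))
        object.__setattr__(
            self, "cluster_labels", tuple(str(c) for c in self.cluster_labels)
        )
        _check_unique(self.marker_names, "marker")
        if ev.ndim != 2 or ev.shape[1] != len(self.marker_names):
            raise TableFormatError(
                f"events shape {ev.shape} does not match "
                f"{len(self.marker_names)} markers"
            )
        if ev.shape[0] != len(self.cluster_labels):
            raise TableFormatError(
                f"{len(self.cluster_labels)} labels for {ev.shape[0]} event rows"
            )
        if ev.shape[0] == 0:
            raise TableFormatError("event matrix has no rows")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def read_cluster_table(
    path: str | Path,
    dialect: str | None = None,
    *,
    pre_transformed: bool = False,
    cofactor: float | None = None,
) -> ClusterExpressionTable:
    """Read a clusters-by-markers CSV/TSV.

    Layout: header row = marker names, first column = cluster ids, all other
    cells numeric.  ``dialect`` forces ``"csv"`` or ``"tsv"``; by default the
    delimiter is sniffed.  Set ``pre_transformed=True`` when the file already
    holds arcsinh values (common for exports from cytometry software), in
    which case ``cofactor`` records the cofactor that was used, if known.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if dialect is None:
        sep = _sniff_delimiter(text[:4096])
    elif dialect == "csv":
        sep = ","
    elif dialect == "tsv":
        sep = "\t"
    else:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")

    rows = list(csv.reader(io.StringIO(text), delimiter=sep))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise TableFormatError(f"{path}: not a clusters-by-markers table")
    header = [c.strip() for c in rows[0][1:]]
    cluster_ids = [r[0].strip() for r in rows[1:]]
    _check_unique(header, "marker")
    _check_unique(cluster_ids, "cluster")

    n_markers = len(header)
    values = np.empty((len(cluster_ids), n_markers), dtype=float)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) - 1 != n_markers:
            raise TableFormatError(
                f"{path}: row {i} has {len(row) - 1} cells, expected {n_markers}"
            )
        for j, cell in enumerate(row[1:], start=1):
            try:
                values[i - 1, j - 1] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric cell {cell.strip()!r} at "
                    f"(row {i}, col {j})"
                ) from None

    if n_markers < MIN_MARKERS or len(cluster_ids) < MIN_CLUSTERS:
        raise DimensionError(
            f"{path}: need at least {MIN_MARKERS} markers and {MIN_CLUSTERS} "
            f"clusters, got {n_markers} markers x {len(cluster_ids)} clusters"
        )
    state = TransformState.ARCSINH if pre_transformed else TransformState.RAW_COUNTS
    return ClusterExpressionTable(
        marker_names=tuple(header),
        cluster_ids=tuple(cluster_ids),
        values=values,
        transform_state=state,
        cofactor=cofactor if pre_transformed else None,
    )


def write_cluster_table(table: ClusterExpressionTable, path: str | Path) -> Path:
    """Write a table back to CSV (inverse of :func:`read_cluster_table`)."""
    path = Path(path)
    table.to_dataframe().to_csv(path)
    return path


def median_by_cluster(
    events: EventMatrix,
    transform_state: TransformState = TransformState.RAW_COUNTS,
    cofactor: float | None = None,
) -> ClusterExpressionTable:
    """Collapse an event matrix to per-cluster medians.

    Output rows follow the order of first appearance of each cluster label;
    an even number of events yields the midpoint of the two central order
    statistics.  The transform state is whatever the caller declares for the
    event values (medians commute with monotone transforms, so the state is
    inherited rather than inferred).
    """
    order: list[str] = []
    seen: set[str] = set()
    for lab in events.cluster_labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    labels = np.asarray(events.cluster_labels)
    medians = np.vstack(
        [np.median(events.events[labels == lab], axis=0) for lab in order]
    )
    return ClusterExpressionTable(
        marker_names=events.marker_names,
        cluster_ids=tuple(order),
        values=medians,
        transform_state=transform_state,
        cofactor=cofactor,
    )


def arcsinh_transform(
    table: ClusterExpressionTable, config: ThresholdConfig | None = None
) -> ClusterExpressionTable:
    """Apply ``asinh(x / cofactor)`` cell-wise to a raw-count table."""
    config = config or ThresholdConfig()
    if table.transform_state is not TransformState.RAW_COUNTS:
        raise TransformStateError(
            "table is already arcsinh-transformed; transforming twice would "
            "distort expression values"
        )
    return replace(
        table,
        values=np.arcsinh(np.asarray(table.values) / config.cofactor),
        transform_state=TransformState.ARCSINH,
        cofactor=config.cofactor,
    )


def apply_zero_threshold(
    table: ClusterExpressionTable, config: ThresholdConfig | None = None
) -> ClusterExpressionTable:
    """Zero every cell strictly below ``zero_cutoff``.

    Applied per cell: a marker may be zeroed (no brick) in one cluster and
    kept in another.  Values exactly at the cutoff survive.  Idempotent.
    """
    config = config or ThresholdConfig()
    if table.transform_state is not TransformState.ARCSINH:
        raise TransformStateError(
            "zeroing threshold is defined on the arcsinh scale; transform first"
        )
    vals = np.asarray(table.values).copy()
    vals[vals < config.zero_cutoff] = 0.0
    return replace(table, values=vals)
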