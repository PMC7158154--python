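"""Dataset-level marker layout: correlation, PCA coordinates, marker groups.

The position of each marker brick is shared by every cluster plot of a
dataset and is derived in three steps:

1. Pearson correlation between every pair of markers, across clusters, on the
   arcsinh-transformed median table (before the zeroing threshold, which is a
   display rule, not an analysis step).  Markers that are co-expressed across
   clusters correlate strongly.
2. PCA with markers as observations and each marker's row of correlations as
   its feature vector (column-centered, unscaled: rows already live on the
   common [-1, 1] scale).  Markers with identical co-expression profiles land
   on the same point; PC1/PC2 are the plot axes, annotated with their
   explained-variance percentages.
3. K-means over the (PC1, PC2) coordinates for a sweep of k values, with the
   elbow of the within-cluster sum of squares (WCSS) curve selecting k.  The
   resulting groups drive brick coloring.

Everything is deterministic given (table, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .data import ClusterExpressionTable, ThresholdConfig, TransformState
from .errors import DimensionError, LayoutError

__all__ = [
    "CorrelationMatrix",
    "PCACoordinates",
    "ElbowResult",
    "MarkerLayout",
    "correlation_matrix",
    "pca_coordinates",
    "kmeans_elbow_groups",
    "build_layout",
    "layout_to_json",
    "layout_from_json",
]

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric marker x marker co-expression correlations in [-1, 1]."""

    marker_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        n = len(self.marker_names)
        if vals.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {vals.shape}")
        if np.max(np.abs(vals - vals.T)) > _SYMMETRY_TOL:
            raise ValueError("correlation matrix is not symmetric")
        if np.any(vals < -1 - 1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be 1")


@dataclass(frozen=True)
class PCACoordinates:
    """Top-2 PCA projection of the correlation rows, plus full spectrum."""

    pc1: np.ndarray
    pc2: np.ndarray
    pc1_var_pct: float
    pc2_var_pct: float
    #: variance percentage of every component (sums to 100)
    all_var_pct: np.ndarray
    #: full coordinates, markers x components (distances in this space equal
    #: distances between centered correlation rows)
    full_coords: np.ndarray


@dataclass(frozen=True)
class ElbowResult:
    """WCSS curve over the tested k values and the selected elbow."""

    k_values: tuple[int, ...]
    wcss: tuple[float, ...]
    k_selected: int


@dataclass(frozen=True)
class MarkerLayout:
    """Per-marker plot position and group, shared by all clusters of a dataset."""

    marker_names: tuple[str, ...]
    pc1: tuple[float, ...]
    pc2: tuple[float, ...]
    pc1_var_pct: float
    pc2_var_pct: float
    group_id: tuple[int, ...]
    k_selected: int
    seed: int
    config: dict = field(default_factory=dict)
    elbow: ElbowResult | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        n = len(self.marker_names)
        if not (len(self.pc1) == len(self.pc2) == len(self.group_id) == n):
            raise ValueError("layout fields must be aligned with marker_names")
        groups = sorted(set(self.group_id))
        if groups != list(range(1, self.k_selected + 1)):
            raise ValueError(
                f"group ids {groups} are not contiguous 1..{self.k_selected}"
            )

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.pc1, self.pc2])

    @property
    def span(self) -> float:
        """Larger of the PC1 and PC2 coordinate ranges (layout units)."""
        return float(max(np.ptp(self.pc1), np.ptp(self.pc2)))


def correlation_matrix(
    table: ClusterExpressionTable, method: str = "pearson"
) -> CorrelationMatrix:
    """Marker-by-marker correlation across clusters.

    Computed on the arcsinh-transformed table *before* thresholding.  A
    zero-variance marker has no defined correlation; it gets 0 off-diagonal
    (and 1 on the diagonal) with a warning, so the layout keeps one position
    per marker.  ``method`` is ``"pearson"`` (default) or ``"spearman"``.
    """
    if table.transform_state is not TransformState.ARCSINH:
        raise LayoutError("correlations are computed on arcsinh-transformed values")
    if table.n_clusters < 3:
        raise DimensionError(
            "correlation needs at least 3 clusters (with 2 every correlation "
            f"is +/-1); got {table.n_clusters}"
        )
    X = np.asarray(table.values, dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata

        X = rankdata(X, axis=0)
    elif method != "pearson":
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")

    degenerate = np.std(X, axis=0) == 0.0
    if degenerate.any():
        names = [m for m, d in zip(table.marker_names, degenerate) if d]
        warnings.warn(
            f"markers with zero variance across clusters: {names}; their "
            "correlations are undefined and set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(marker_names=table.marker_names, values=corr)


def pca_coordinates(corr: CorrelationMatrix) -> PCACoordinates:
    """Project markers into PC1/PC2 space.

    Markers are the observations; each marker's feature vector is its row of
    correlations.  Rows are column-centered (no re-scaling) and decomposed by
    SVD.  The sign of each component is fixed so that its largest-magnitude
    loading (first such index on ties) is positive, making the layout
    reproducible across BLAS implementations.
    """
    X = np.asarray(corr.values, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(s > 1e-12):
        raise LayoutError(
            "all markers have identical correlation profiles after centering; "
            "the layout is undefined"
        )
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U * s  # projections onto the principal axes
    ev = s**2
    var_pct = 100.0 * ev / ev.sum()
    pc2 = coords[:, 1] if coords.shape[1] > 1 else np.zeros(len(X))
    pc2_var = float(var_pct[1]) if len(var_pct) > 1 else 0.0
    return PCACoordinates(
        pc1=coords[:, 0],
        pc2=pc2,
        pc1_var_pct=float(var_pct[0]),
        pc2_var_pct=pc2_var,
        all_var_pct=var_pct,
        full_coords=coords,
    )


def _select_elbow(k_values: np.ndarray, wcss: np.ndarray) -> int:
    """Largest discrete second difference of log(WCSS); ties -> smallest k.

    The log scale makes the curvature measure scale-invariant: on raw WCSS
    the huge absolute drop from k=1 to k=2 dominates the second difference
    and drags the elbow toward k=2 even when the curve clearly flattens
    later.  WCSS values are floored at a tiny fraction of the k=1 value so
    exact zeros (perfectly separable points) stay finite.  With fewer than 3
    tested values there is no interior point, so the smallest k already
    reaching the minimum WCSS (within a relative 1e-9) is chosen.
    """
    if len(k_values) >= 3:
        floor = 1e-12 * max(float(wcss[0]), 1.0)
        lw = np.log(np.maximum(wcss, floor))
        d2 = lw[:-2] - 2.0 * lw[1:-1] + lw[2:]
        return int(k_values[1 + int(np.argmax(d2))])
    tol = 1e-9 * max(1.0, float(wcss.max()))
    best = float(wcss.min())
    for k, w in zip(k_values, wcss):
        if w <= best + tol:
            return int(k)
    return int(k_values[-1])  # pragma: no cover


def kmeans_elbow_groups(
    coords: np.ndarray,
    k_min: int = 1,
    k_max: int | None = None,
    n_k: int = 30,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, ElbowResult]:
    """Group markers by K-means with the k chosen at the WCSS elbow.

    ``coords`` is markers x 2 (the PC1/PC2 positions, or any embedding).  Up
    to ``n_k`` integer k values evenly spaced in [k_min, k_max] are tested
    (all of them when the range holds <= n_k integers); each run uses
    ``n_restarts`` seeded k-means++ restarts.  Group labels are renumbered
    1..k by order of first appearance in marker order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be a 2-D array (markers x dims)")
    n = coords.shape[0]
    if k_max is None:
        k_max = n
    if not (1 <= k_min <= k_max <= n):
        raise ValueError(f"need 1 <= k_min <= k_max <= {n}, got [{k_min}, {k_max}]")
    n_distinct = len(np.unique(coords, axis=0))
    if k_max > n_distinct:
        warnings.warn(
            f"only {n_distinct} distinct marker positions; reducing k_max "
            f"from {k_max} to {n_distinct}",
            stacklevel=2,
        )
        k_max = n_distinct
        k_min = min(k_min, k_max)

    ks = np.unique(np.round(np.linspace(k_min, k_max, min(n_k, k_max - k_min + 1))).astype(int))
    rs = int(seed) & 0x7FFFFFFF
    wcss = np.empty(len(ks))
    labels_by_k: dict[int, np.ndarray] = {}
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=n_restarts, random_state=rs)
        labels_by_k[int(k)] = km.fit_predict(coords)
        wcss[i] = float(km.inertia_)

    k_sel = _select_elbow(ks, wcss)
    raw = labels_by_k[k_sel]
    remap: dict[int, int] = {}
    for lab in raw:
        if int(lab) not in remap:
            remap[int(lab)] = len(remap) + 1
    groups = np.array([remap[int(lab)] for lab in raw], dtype=int)
    elbow = ElbowResult(
        k_values=tuple(int(k) for k in ks),
        wcss=tuple(float(w) for w in wcss),
        k_selected=int(k_sel),
    )
    return groups, elbow


def build_layout(
    table: ClusterExpressionTable,
    config: ThresholdConfig | None = None,
    seed: int = 0,
    *,
    k_min: int = 1,
    k_max: int | None = None,
    n_k: int = 30,
    correlation_method: str = "pearson",
    cluster_on: str = "coords",
) -> MarkerLayout:
    """Compute the dataset-level marker layout.

    Orchestrates correlation -> PCA -> elbow K-means.  ``cluster_on`` selects
    the K-means feature space: ``"coords"`` (the plotted 2-D positions,
    default) or ``"rows"`` (full centered correlation rows).  The result is a
    pure function of (table, options, seed) and is reused unchanged by every
    cluster's brick plot.
    """
    config = config or ThresholdConfig()
    if table.n_markers < 3 or table.n_clusters < 3:
        raise DimensionError(
            f"layout needs >= 3 markers and >= 3 clusters, got "
            f"{table.n_markers} x {table.n_clusters}"
        )
    corr = correlation_matrix(table, method=correlation_method)
    pca = pca_coordinates(corr)
    if cluster_on == "coords":
        feats = np.column_stack([pca.pc1, pca.pc2])
    elif cluster_on == "rows":
        feats = pca.full_coords  # isometric to centered correlation rows
    else:
        raise ValueError(f"cluster_on must be 'coords' or 'rows', got {cluster_on!r}")
    groups, elbow = kmeans_elbow_groups(
        feats, k_min=k_min, k_max=k_max, n_k=n_k, seed=seed
    )
    return MarkerLayout(
        marker_names=table.marker_names,
        pc1=tuple(float(v) for v in pca.pc1),
        pc2=tuple(float(v) for v in pca.pc2),
        pc1_var_pct=pca.pc1_var_pct,
        pc2_var_pct=pca.pc2_var_pct,
        group_id=tuple(int(g) for g in groups),
        k_selected=elbow.k_selected,
        seed=int(seed),
        config={
            "zero_cutoff": config.zero_cutoff,
            "cofactor": config.cofactor,
            "k_min": k_min,
            "k_max": k_max,
            "n_k": n_k,
            "correlation_method": correlation_method,
            "cluster_on": cluster_on,
        },
        elbow=elbow,
    )


def layout_to_json(layout: MarkerLayout) -> str:
    """Serialize a layout to the JSON contract consumed by rendering."""
    doc = {
        "markers": [
            {"name": m, "pc1": x, "pc2": y, "group": g}
            for m, x, y, g in zip(
                layout.marker_names, layout.pc1, layout.pc2, layout.group_id
            )
        ],
        "pc1_var_pct": layout.pc1_var_pct,
        "pc2_var_pct": layout.pc2_var_pct,
        "k_selected": layout.k_selected,
        "seed": layout.seed,
        "config": layout.config,
    }
    return json.dumps(doc, indent=2)


def layout_from_json(text: str | Path) -> MarkerLayout:
    if isinstance(text, Path):
        text = text.read_text()
    doc = json.loads(text)
    return MarkerLayout(
        marker_names=tuple(m["name"] for m in doc["markers"]),
        pc1=tuple(m["pc1"] for m in doc["markers"]),
        pc2=tuple(m["pc2"] for m in doc["markers"]),
        pc1_var_pct=doc["pc1_var_pct"],
        pc2_var_pct=doc["pc2_var_pct"],
        group_id=tuple(m["group"] for m in doc["markers"]),
        k_selected=doc["k_selected"],
        seed=doc["seed"],
        config=doc.get("config", {}),
    )
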