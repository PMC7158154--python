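"""Brick sizing and overlap-free placement for a single cluster plot.

Each marker becomes a square brick centered at its dataset-level layout
position, with area proportional to the cluster's (thresholded, arcsinh)
expression of that marker — so one marker twice as expressed in cluster B as
in cluster A gets exactly twice the area.  A zero value gives no brick.  One
area-per-expression-unit scale factor is shared across all clusters of a
dataset, which is what makes brick sizes comparable between cluster plots.

Because correlated markers sit close together, bricks frequently overlap at
their raw positions.  Overlaps are removed by a deterministic local rule:
bricks are placed largest-first, and a brick that lands on an already-placed
one is pushed outward along the ray from the blocker's center through its own
original center until the two are edge-adjacent; cascading collisions repeat
the push, with a bounded deterministic spiral search as a fallback.  Bricks
that never collide are never moved.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data import ClusterExpressionTable, TransformState
from .errors import (
    AlignmentError,
    OverlapResolutionError,
    ScaleError,
    TransformStateError,
)
from .layout import MarkerLayout

__all__ = [
    "Brick",
    "BrickPlot",
    "GeometryConfig",
    "compute_scale_factor",
    "size_bricks",
    "resolve_overlaps",
    "build_brick_plot",
    "plot_to_json",
    "plot_from_json",
    "interiors_overlap",
]

#: numeric slack for the interior-disjointness test: rectangles closer than
#: this along both axes count as overlapping; exact edge contact does not.
OVERLAP_EPS = 1e-9


@dataclass(frozen=True)
class GeometryConfig:
    """Brick sizing/placement options.

    ``max_area_fraction`` sets the side of the single largest brick in the
    dataset as a fraction of the layout coordinate span.  ``scale_mode`` is
    ``"global"`` (one linear area scale for the whole dataset, default) or
    ``"per_marker"`` (each marker first normalized by its own dataset-wide
    maximum — sizes then compare within a marker but not between markers).
    ``aspect_ratio`` is brick width/height at equal area (1.0 = squares).
    """

    max_area_fraction: float = 0.2
    scale_mode: str = "global"
    aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.max_area_fraction <= 1:
            raise ValueError("max_area_fraction must be in (0, 1]")
        if self.scale_mode not in ("global", "per_marker"):
            raise ValueError("scale_mode must be 'global' or 'per_marker'")
        if not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be positive")


@dataclass(frozen=True)
class Brick:
    """One marker's square in one cluster plot (layout units)."""

    marker_name: str
    center_x: float
    center_y: float
    side: float  # sqrt(area); width/height may differ if aspect != 1
    area: float
    group_id: int
    zeroed: bool
    displaced: bool = False

    def __post_init__(self) -> None:
        if abs(self.area - self.side**2) > 1e-12 * max(1.0, self.area):
            raise ValueError(f"area {self.area} != side^2 {self.side**2}")
        if self.zeroed != (self.area == 0.0):
            raise ValueError("zeroed flag must match area == 0")

    def half_extents(self, aspect_ratio: float = 1.0) -> tuple[float, float]:
        r = math.sqrt(aspect_ratio)
        return (self.side * r / 2.0, self.side / r / 2.0)


@dataclass(frozen=True)
class BrickPlot:
    """All bricks of one cluster, overlap-resolved and render-ready."""

    cluster_id: str
    bricks: tuple[Brick, ...]
    layout_ref: str  # fingerprint of the MarkerLayout these positions came from
    scale_factor: float
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    aspect_ratio: float = 1.0

    @property
    def rendered_bricks(self) -> tuple[Brick, ...]:
        return tuple(b for b in self.bricks if not b.zeroed)


def layout_fingerprint(layout: MarkerLayout) -> str:
    from .layout import layout_to_json

    return hashlib.sha1(layout_to_json(layout).encode()).hexdigest()[:12]


def compute_scale_factor(
    table: ClusterExpressionTable,
    layout: MarkerLayout,
    max_area_fraction: float = 0.2,
) -> float:
    """Area units per expression unit, one value per dataset.

    Chosen so the single largest brick anywhere in the (thresholded) dataset
    has side ``max_area_fraction * span``, where span is the larger of the
    layout's PC1/PC2 coordinate ranges: ``s = (f * L)**2 / v_max``.  Doubling
    every table value halves ``s``, leaving rendered sizes unchanged.
    """
    if table.transform_state is not TransformState.ARCSINH:
        raise TransformStateError("scale factor is defined on transformed values")
    v_max = float(np.max(table.values))
    if v_max <= 0:
        raise ScaleError("no bricks to scale: every value in the table is zero")
    span = layout.span
    if span <= 0:
        span = 1.0  # all markers coincide; fall back to a unit canvas
    return (max_area_fraction * span) ** 2 / v_max


def size_bricks(
    layout: MarkerLayout,
    cluster_row: np.ndarray,
    scale_factor: float,
) -> list[Brick]:
    """Turn one cluster's thresholded expression row into positioned bricks."""
    row = np.asarray(cluster_row, dtype=float)
    if row.shape != (len(layout.marker_names),):
        raise AlignmentError(
            f"cluster row has {row.shape} values for {len(layout.marker_names)} "
            "layout markers"
        )
    bricks = []
    for name, x, y, g, v in zip(layout.marker_names, layout.pc1, layout.pc2, layout.group_id, row):
        area = scale_factor * float(v)
        bricks.append(
            Brick(
                marker_name=name,
                center_x=float(x),
                center_y=float(y),
                side=math.sqrt(area),
                area=area,
                group_id=int(g),
                zeroed=(area == 0.0),
            )
        )
    return bricks


def interiors_overlap(
    a: Brick, b: Brick, aspect_ratio: float = 1.0, eps: float = OVERLAP_EPS
) -> bool:
    """True if the open interiors of two bricks intersect (edge contact ok)."""
    ahx, ahy = a.half_extents(aspect_ratio)
    bhx, bhy = b.half_extents(aspect_ratio)
    return (
        abs(a.center_x - b.center_x) < ahx + bhx - eps
        and abs(a.center_y - b.center_y) < ahy + bhy - eps
    )


def _push_until_adjacent(
    moving: Brick,
    blocker: Brick,
    origin: tuple[float, float],
    aspect_ratio: float,
) -> Brick:
    """Translate ``moving`` along the ray blocker-center -> ``origin`` until
    the two rectangles are exactly edge-adjacent.

    ``origin`` is the moving brick's original (pre-resolution) center; when it
    coincides with the blocker's center the push direction degenerates and a
    fixed +x fallback is used.
    """
    dx = origin[0] - blocker.center_x
    dy = origin[1] - blocker.center_y
    norm = math.hypot(dx, dy)
    if norm < 1e-12:
        dx, dy = 1.0, 0.0
    else:
        dx, dy = dx / norm, dy / norm
    mhx, mhy = moving.half_extents(aspect_ratio)
    bhx, bhy = blocker.half_extents(aspect_ratio)
    sep_x = mhx + bhx
    sep_y = mhy + bhy
    ox = moving.center_x - blocker.center_x
    oy = moving.center_y - blocker.center_y
    # minimal t > 0 with |ox + t*dx| = sep_x (or same on y); take the axis
    # reached first, i.e. the smaller t, then snap that axis exactly.
    t_candidates = []
    if dx != 0.0:
        t = ((sep_x if dx > 0 else -sep_x) - ox) / dx
        if t > 0:
            t_candidates.append((t, "x"))
    if dy != 0.0:
        t = ((sep_y if dy > 0 else -sep_y) - oy) / dy
        if t > 0:
            t_candidates.append((t, "y"))
    if not t_candidates:  # already separated along the ray; nothing to do
        return moving
    t, axis = min(t_candidates)
    nx = moving.center_x + t * dx
    ny = moving.center_y + t * dy
    if axis == "x":  # snap to exact adjacency on the limiting axis
        nx = blocker.center_x + math.copysign(sep_x, nx - blocker.center_x)
    else:
        ny = blocker.center_y + math.copysign(sep_y, ny - blocker.center_y)
    return replace(moving, center_x=nx, center_y=ny, displaced=True)


def _spiral_place(
    brick: Brick,
    origin: tuple[float, float],
    placed: list[Brick],
    aspect_ratio: float,
    angle_steps: int = 32,
    radial_step_frac: float = 0.25,
    max_rings: int = 2000,
) -> Brick:
    """Deterministic outward ring search for the nearest collision-free spot.

    Rings of radius ``m * radial_step_frac * side`` around the original
    center are scanned at ``angle_steps`` fixed angles (starting at +x,
    counter-clockwise); the first free position wins.
    """
    step = radial_step_frac * max(brick.side, OVERLAP_EPS)
    for ring in range(1, max_rings + 1):
        r = ring * step
        for j in range(angle_steps):
            theta = 2.0 * math.pi * j / angle_steps
            cand = replace(
                brick,
                center_x=origin[0] + r * math.cos(theta),
                center_y=origin[1] + r * math.sin(theta),
                displaced=True,
            )
            if not any(interiors_overlap(cand, p, aspect_ratio) for p in placed):
                return cand
    raise OverlapResolutionError(
        "overlap resolution could not find a free position; total brick area "
        "exceeds the canvas — try a smaller max_area_fraction"
    )


def resolve_overlaps(
    bricks: list[Brick],
    aspect_ratio: float = 1.0,
    max_push_iters: int = 64,
) -> list[Brick]:
    """Remove brick overlaps by deterministic local displacement.

    Bricks with no initial overlap are immovable obstacles: they keep their
    exact input coordinates no matter what.  The remaining non-zeroed bricks
    are placed one at a time in descending-area order (ties broken by marker
    name).  A brick intersecting an already-placed one is pushed outward from
    that blocker along the ray through its own original center until
    edge-adjacent; if the new spot hits another placed brick the push repeats
    against it, and after ``max_push_iters`` pushes a deterministic spiral
    search around the original center takes over.  Output order equals input
    order; moved bricks carry ``displaced=True``.
    """
    active = [i for i, b in enumerate(bricks) if not b.zeroed]
    free = {
        i
        for i in active
        if not any(
            interiors_overlap(bricks[i], bricks[j], aspect_ratio)
            for j in active
            if j != i
        )
    }
    order = sorted(
        (i for i in active if i not in free),
        key=lambda i: (-bricks[i].area, bricks[i].marker_name),
    )
    placed: list[Brick] = [bricks[i] for i in sorted(free)]
    out: dict[int, Brick] = {}
    for i in order:
        cur = bricks[i]
        origin = (cur.center_x, cur.center_y)
        pushes = 0
        while True:
            blocker = next(
                (p for p in placed if interiors_overlap(cur, p, aspect_ratio)), None
            )
            if blocker is None:
                break
            if pushes >= max_push_iters:
                cur = _spiral_place(cur, origin, placed, aspect_ratio)
                break
            cur = _push_until_adjacent(cur, blocker, origin, aspect_ratio)
            pushes += 1
        placed.append(cur)
        out[i] = cur
    return [out.get(i, b) for i, b in enumerate(bricks)]


def build_brick_plot(
    table: ClusterExpressionTable,
    layout: MarkerLayout,
    cluster_id: str,
    config: GeometryConfig | None = None,
) -> BrickPlot:
    """Size, place, and de-overlap all bricks for one cluster.

    ``table`` must already be thresholded; its marker set must match the
    layout.  The scale factor is computed from the whole table, so every
    cluster of the dataset shares it.
    """
    config = config or GeometryConfig()
    if table.marker_names != layout.marker_names:
        raise AlignmentError(
            "table and layout marker sets differ; build the layout from the "
            "same table"
        )
    values = np.asarray(table.values, dtype=float)
    if config.scale_mode == "per_marker":
        col_max = values.max(axis=0)
        safe = np.where(col_max > 0, col_max, 1.0)
        values = values / safe
        norm_table = ClusterExpressionTable(
            marker_names=table.marker_names,
            cluster_ids=table.cluster_ids,
            values=values,
            transform_state=table.transform_state,
            cofactor=table.cofactor,
        )
    else:
        norm_table = table
    scale = compute_scale_factor(norm_table, layout, config.max_area_fraction)
    row = values[list(table.cluster_ids).index(str(cluster_id))] if str(
        cluster_id
    ) in table.cluster_ids else None
    if row is None:
        # delegate error message (lists available ids)
        table.cluster_row(cluster_id)
        raise AssertionError("unreachable")
    bricks = size_bricks(layout, row, scale)
    bricks = resolve_overlaps(bricks, aspect_ratio=config.aspect_ratio)
    rendered = [b for b in bricks if not b.zeroed]
    if rendered:
        hx, hy = zip(*(b.half_extents(config.aspect_ratio) for b in rendered))
        xs = np.array([b.center_x for b in rendered])
        ys = np.array([b.center_y for b in rendered])
        bounds = (
            float(np.min(xs - hx)),
            float(np.min(ys - hy)),
            float(np.max(xs + hx)),
            float(np.max(ys + hy)),
        )
    else:
        bounds = (
            float(min(layout.pc1)),
            float(min(layout.pc2)),
            float(max(layout.pc1)),
            float(max(layout.pc2)),
        )
    return BrickPlot(
        cluster_id=str(cluster_id),
        bricks=tuple(bricks),
        layout_ref=layout_fingerprint(layout),
        scale_factor=scale,
        bounds=bounds,
        aspect_ratio=config.aspect_ratio,
    )


def plot_to_json(plot: BrickPlot) -> str:
    """Serialize a brick plot to the renderer's JSON contract (stable order)."""
    doc = {
        "cluster_id": plot.cluster_id,
        "layout_ref": plot.layout_ref,
        "scale_factor": plot.scale_factor,
        "aspect_ratio": plot.aspect_ratio,
        "bounds": list(plot.bounds),
        "bricks": [
            {
                "marker": b.marker_name,
                "x": b.center_x,
                "y": b.center_y,
                "side": b.side,
                "group": b.group_id,
                "zeroed": b.zeroed,
                "displaced": b.displaced,
            }
            for b in plot.bricks
        ],
    }
    return json.dumps(doc, indent=2)


def plot_from_json(text: str | Path) -> BrickPlot:
    if isinstance(text, Path):
        text = text.read_text()
    doc = json.loads(text)
    bricks = tuple(
        Brick(
            marker_name=b["marker"],
            center_x=b["x"],
            center_y=b["y"],
            side=b["side"],
            area=b["side"] ** 2,
            group_id=b["group"],
            zeroed=b["zeroed"],
            displaced=b["displaced"],
        )
        for b in doc["bricks"]
    )
    return BrickPlot(
        cluster_id=doc["cluster_id"],
        bricks=bricks,
        layout_ref=doc["layout_ref"],
        scale_factor=doc["scale_factor"],
        bounds=tuple(doc["bounds"]),
        aspect_ratio=doc.get("aspect_ratio", 1.0),
    )
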