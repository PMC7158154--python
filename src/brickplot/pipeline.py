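"""End-to-end pipeline: table in, layout + per-cluster brick plots out.

``run_pipeline`` chains ingestion (optionally collapsing per-event data to
medians), arcsinh transform, zeroing threshold, dataset-level layout, and
per-cluster geometry + rendering.  All artifacts are written to one output
directory:

    layout.json              marker positions/groups (dataset-level contract)
    elbow.json               k vs WCSS diagnostic and the selected k
    plots/<cluster>.json     positioned, de-overlapped bricks per cluster
    plots/<cluster>.<fmt>    rendered figure per cluster
    manifest.json            seed, options, package version, input checksum

Rerunning with the same input and seed reproduces layout.json and every plot
JSON byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .data import (
    ClusterExpressionTable,
    EventMatrix,
    ThresholdConfig,
    TransformState,
    apply_zero_threshold,
    arcsinh_transform,
    median_by_cluster,
    read_cluster_table,
)
from .errors import TableFormatError
from .geometry import GeometryConfig, build_brick_plot, plot_to_json
from .layout import build_layout, layout_to_json
from .render import PALETTES, RenderConfig, render_plot

log = logging.getLogger("brickplot")

__all__ = ["PipelineOptions", "run_pipeline", "read_event_table"]


@dataclass(frozen=True)
class PipelineOptions:
    """Everything configurable about a pipeline run (CLI flags mirror this)."""

    events: bool = False
    label_col: str | None = None
    dialect: str | None = None
    pre_transformed: bool = False
    cofactor: float = 5.0
    threshold: float = 1.0
    k_min: int = 1
    k_max: int | None = None
    n_k: int = 30
    seed: int = 42
    correlation_method: str = "pearson"
    cluster_on: str = "coords"
    scale_mode: str = "global"
    max_area_fraction: float = 0.2
    aspect_ratio: float = 1.0
    output_format: str = "svg"
    palette: str = "okabe-ito"
    label_mode: str = "all"
    cluster_id: str | None = None


def read_event_table(
    path: str | Path, label_col: str, dialect: str | None = None
) -> EventMatrix:
    """Read an events-by-markers CSV/TSV with a named cluster-label column."""
    path = Path(path)
    from .data import _sniff_delimiter

    text = path.read_text(encoding="utf-8")
    sep = {"csv": ",", "tsv": "\t"}.get(dialect) or _sniff_delimiter(text[:4096])
    rows = [r for r in csv.reader(text.splitlines(), delimiter=sep) if any(r)]
    header = [c.strip() for c in rows[0]]
    if label_col not in header:
        raise TableFormatError(
            f"{path}: cluster-label column {label_col!r} not in header {header}"
        )
    li = header.index(label_col)
    markers = [h for i, h in enumerate(header) if i != li]
    labels = []
    values = np.empty((len(rows) - 1, len(markers)))
    for i, row in enumerate(rows[1:], start=1):
        labels.append(row[li].strip())
        k = 0
        for j, cell in enumerate(row):
            if j == li:
                continue
            try:
                values[i - 1, k] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric cell {cell.strip()!r} at "
                    f"(row {i}, col {j + 1})"
                ) from None
            k += 1
    return EventMatrix(
        marker_names=tuple(markers), events=values, cluster_labels=tuple(labels)
    )


def _safe_name(cluster_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", cluster_id)


def run_pipeline(
    input_path: str | Path,
    out_dir: str | Path,
    options: PipelineOptions | None = None,
) -> Path:
    """Run the full brick-plot pipeline; returns the output directory."""
    options = options or PipelineOptions()
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "plots").mkdir(exist_ok=True)

    config = ThresholdConfig(zero_cutoff=options.threshold, cofactor=options.cofactor)

    log.info("reading %s", input_path)
    if options.events:
        if not options.label_col:
            raise TableFormatError("per-event input requires --label-col")
        events = read_event_table(input_path, options.label_col, options.dialect)
        state = (
            TransformState.ARCSINH
            if options.pre_transformed
            else TransformState.RAW_COUNTS
        )
        table = median_by_cluster(events, transform_state=state)
        log.info(
            "collapsed %d events to %d cluster medians",
            events.events.shape[0],
            table.n_clusters,
        )
    else:
        table = read_cluster_table(
            input_path, options.dialect, pre_transformed=options.pre_transformed
        )
    log.info("table: %d clusters x %d markers", table.n_clusters, table.n_markers)

    if table.transform_state is TransformState.RAW_COUNTS:
        log.info("arcsinh transform, cofactor %g", config.cofactor)
        table = arcsinh_transform(table, config)

    log.info("building layout (seed %d)", options.seed)
    layout = build_layout(
        table,
        config,
        seed=options.seed,
        k_min=options.k_min,
        k_max=options.k_max,
        n_k=options.n_k,
        correlation_method=options.correlation_method,
        cluster_on=options.cluster_on,
    )
    log.info(
        "layout: k=%d groups, PC1 %.1f%% / PC2 %.1f%% variance",
        layout.k_selected,
        layout.pc1_var_pct,
        layout.pc2_var_pct,
    )
    (out_dir / "layout.json").write_text(layout_to_json(layout))
    assert layout.elbow is not None
    (out_dir / "elbow.json").write_text(
        json.dumps(
            {
                "k_values": list(layout.elbow.k_values),
                "wcss": list(layout.elbow.wcss),
                "k_selected": layout.elbow.k_selected,
            },
            indent=2,
        )
    )

    log.info("zeroing threshold %g", config.zero_cutoff)
    thresholded = apply_zero_threshold(table, config)

    geom = GeometryConfig(
        max_area_fraction=options.max_area_fraction,
        scale_mode=options.scale_mode,
        aspect_ratio=options.aspect_ratio,
    )
    palette = PALETTES.get(options.palette)
    if palette is None:
        palette = tuple(options.palette.split(","))
    render_cfg = RenderConfig(
        palette=palette,
        label_mode=options.label_mode,
        output_format=options.output_format,
    )

    targets = (
        [options.cluster_id] if options.cluster_id is not None else list(table.cluster_ids)
    )
    for cid in targets:
        plot = build_brick_plot(thresholded, layout, cid, geom)
        stem = out_dir / "plots" / _safe_name(cid)
        stem.with_suffix(".json").write_text(plot_to_json(plot))
        render_plot(
            plot, layout, render_cfg, stem.with_suffix(f".{options.output_format}")
        )
        log.info(
            "cluster %s: %d bricks rendered, %d zeroed",
            cid,
            len(plot.rendered_bricks),
            len(plot.bricks) - len(plot.rendered_bricks),
        )

    manifest = {
        "brickplot_version": __version__,
        "seed": options.seed,
        "options": asdict(options),
        "input": str(input_path),
        "input_sha256": hashlib.sha256(input_path.read_bytes()).hexdigest(),
        "n_clusters": table.n_clusters,
        "n_markers": table.n_markers,
        "k_selected": layout.k_selected,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %s", out_dir / "manifest.json")
    return out_dir
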