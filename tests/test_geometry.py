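"""Brick sizing, global area scale, and overlap resolution."""

import itertools
import math

import numpy as np
import pytest

from brickplot import (
    Brick,
    ClusterExpressionTable,
    GeometryConfig,
    ThresholdConfig,
    TransformState,
    apply_zero_threshold,
    build_brick_plot,
    compute_scale_factor,
    plot_from_json,
    plot_to_json,
    resolve_overlaps,
    size_bricks,
)
from brickplot.errors import AlignmentError, ClusterLookupError, ScaleError
from brickplot.geometry import interiors_overlap


def overlap_oracle(bricks, eps=1e-9):
    """O(n^2) pairwise open-interior intersection check on squares."""
    violations = []
    rendered = [b for b in bricks if not b.zeroed]
    for a, b in itertools.combinations(rendered, 2):
        if (
            abs(a.center_x - b.center_x) < (a.side + b.side) / 2 - eps
            and abs(a.center_y - b.center_y) < (a.side + b.side) / 2 - eps
        ):
            violations.append((a.marker_name, b.marker_name))
    return violations


def make_brick(name, x, y, side, group=1):
    return Brick(
        marker_name=name,
        center_x=float(x),
        center_y=float(y),
        side=float(side),
        area=float(side) ** 2,
        group_id=group,
        zeroed=(side == 0.0),
    )


class TestScaleFactor:
    def test_algebraic_inversion(self, synthetic_thresholded, synthetic_layout):
        f = 0.2
        s = compute_scale_factor(synthetic_thresholded, synthetic_layout, f)
        v_max = float(np.max(synthetic_thresholded.values))
        assert s == pytest.approx((f * synthetic_layout.span) ** 2 / v_max)
        # the single largest brick gets side = f * span
        assert math.sqrt(s * v_max) == pytest.approx(f * synthetic_layout.span)

    def test_doubling_values_halves_scale(self, synthetic_thresholded, synthetic_layout):
        t = synthetic_thresholded
        doubled = ClusterExpressionTable(
            marker_names=t.marker_names,
            cluster_ids=t.cluster_ids,
            values=2.0 * np.asarray(t.values),
            transform_state=t.transform_state,
            cofactor=t.cofactor,
        )
        s1 = compute_scale_factor(t, synthetic_layout)
        s2 = compute_scale_factor(doubled, synthetic_layout)
        assert s2 == pytest.approx(s1 / 2.0, rel=1e-12)

    def test_all_zero_table_rejected(self, synthetic_layout, synthetic_thresholded):
        t = synthetic_thresholded
        zero = ClusterExpressionTable(
            marker_names=t.marker_names,
            cluster_ids=t.cluster_ids,
            values=np.zeros_like(np.asarray(t.values)),
            transform_state=TransformState.ARCSINH,
        )
        with pytest.raises(ScaleError):
            compute_scale_factor(zero, synthetic_layout)


class TestSizeBricks:
    def test_area_proportional_to_value(self, synthetic_layout):
        n = len(synthetic_layout.marker_names)
        row = np.zeros(n)
        row[0], row[1] = 1.2, 2.4
        bricks = size_bricks(synthetic_layout, row, scale_factor=0.5)
        assert bricks[1].area == pytest.approx(2.0 * bricks[0].area, rel=1e-12)
        assert bricks[1].side == pytest.approx(math.sqrt(2.0) * bricks[0].side)

    def test_zero_value_gives_zeroed_brick(self, synthetic_layout):
        row = np.ones(len(synthetic_layout.marker_names))
        row[3] = 0.0
        bricks = size_bricks(synthetic_layout, row, 1.0)
        assert bricks[3].zeroed and bricks[3].area == 0.0
        assert not bricks[0].zeroed

    def test_constant_row_gives_congruent_squares(self, synthetic_layout):
        bricks = size_bricks(
            synthetic_layout, np.full(len(synthetic_layout.marker_names), 2.0), 0.3
        )
        sides = {b.side for b in bricks}
        assert len(sides) == 1

    def test_marker_count_mismatch_rejected(self, synthetic_layout):
        with pytest.raises(AlignmentError):
            size_bricks(synthetic_layout, np.ones(3), 1.0)

    def test_positions_copied_from_layout(self, synthetic_layout):
        bricks = size_bricks(
            synthetic_layout, np.ones(len(synthetic_layout.marker_names)), 1.0
        )
        for b, x, y, g in zip(
            bricks, synthetic_layout.pc1, synthetic_layout.pc2, synthetic_layout.group_id
        ):
            assert (b.center_x, b.center_y, b.group_id) == (x, y, g)


class TestResolveOverlaps:
    def test_disjoint_input_is_noop(self):
        bricks = [
            make_brick("a", 0, 0, 1.0),
            make_brick("b", 5, 0, 1.0),
            make_brick("c", 0, 5, 2.0),
        ]
        out = resolve_overlaps(bricks)
        assert out == bricks
        assert not any(b.displaced for b in out)

    def test_coincident_pair_pushed_along_plus_x(self):
        # ties in area break by name: "a" stays, "b" is pushed; a zero-length
        # ray falls back to +x, landing edge-adjacent at distance 1
        out = resolve_overlaps([make_brick("a", 0, 0, 1.0), make_brick("b", 0, 0, 1.0)])
        assert (out[0].center_x, out[0].center_y) == (0.0, 0.0)
        assert out[0].displaced is False
        assert (out[1].center_x, out[1].center_y) == (1.0, 0.0)
        assert out[1].displaced is True
        assert not overlap_oracle(out)

    def test_random_configurations_end_disjoint(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 15))
            bricks = [
                make_brick(
                    f"m{i:02d}",
                    rng.uniform(-2, 2),
                    rng.uniform(-2, 2),
                    float(np.exp(rng.uniform(np.log(0.05), np.log(1.0)))),
                )
                for i in range(n)
            ]
            out = resolve_overlaps(bricks)
            assert overlap_oracle(out) == []
            # non-colliding bricks keep bit-identical positions
            for b_in, b_out in zip(bricks, out):
                collided = any(
                    interiors_overlap(b_in, other)
                    for other in bricks
                    if other is not b_in
                )
                if not collided:
                    assert (b_out.center_x, b_out.center_y) == (
                        b_in.center_x,
                        b_in.center_y,
                    )
                    assert not b_out.displaced

    def test_deterministic_across_runs(self, rng):
        bricks = [
            make_brick(f"m{i}", rng.uniform(-1, 1), rng.uniform(-1, 1), 0.5)
            for i in range(10)
        ]
        a = resolve_overlaps(list(bricks))
        b = resolve_overlaps(list(bricks))
        assert a == b

    def test_preserves_input_order_and_areas(self, rng):
        bricks = [
            make_brick(f"m{i}", rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5), 0.4 + 0.1 * i)
            for i in range(6)
        ]
        out = resolve_overlaps(bricks)
        assert [b.marker_name for b in out] == [b.marker_name for b in bricks]
        for b_in, b_out in zip(bricks, out):
            assert b_out.area == b_in.area  # translation only, never rescaling


class TestBuildBrickPlot:
    def test_unknown_cluster_id(self, synthetic_thresholded, synthetic_layout):
        with pytest.raises(ClusterLookupError, match="available"):
            build_brick_plot(synthetic_thresholded, synthetic_layout, "missing")

    def test_all_zero_cluster_is_legal(self, synthetic_layout, synthetic_thresholded):
        t = synthetic_thresholded
        vals = np.asarray(t.values).copy()
        vals[0] = 0.0
        table = ClusterExpressionTable(
            marker_names=t.marker_names,
            cluster_ids=t.cluster_ids,
            values=vals,
            transform_state=t.transform_state,
        )
        plot = build_brick_plot(table, synthetic_layout, table.cluster_ids[0])
        assert plot.rendered_bricks == ()
        assert len(plot.bricks) == len(synthetic_layout.marker_names)

    def test_positions_shared_across_clusters_pre_displacement(
        self, synthetic_thresholded, synthetic_layout
    ):
        # dataset-level marker map: undisplaced bricks of any two clusters sit
        # at identical layout coordinates
        p1 = build_brick_plot(synthetic_thresholded, synthetic_layout, "C01")
        p2 = build_brick_plot(synthetic_thresholded, synthetic_layout, "C02")
        for b1, b2 in zip(p1.bricks, p2.bricks):
            if not (b1.displaced or b2.displaced or b1.zeroed or b2.zeroed):
                assert (b1.center_x, b1.center_y) == (b2.center_x, b2.center_y)

    def test_scale_factor_shared_and_areas_proportional(
        self, synthetic_thresholded, synthetic_layout
    ):
        plots = [
            build_brick_plot(synthetic_thresholded, synthetic_layout, cid)
            for cid in synthetic_thresholded.cluster_ids[:6]
        ]
        scale = plots[0].scale_factor
        values = np.asarray(synthetic_thresholded.values)
        for k, plot in enumerate(plots):
            assert plot.scale_factor == scale
            for j, b in enumerate(plot.bricks):
                assert b.area == pytest.approx(scale * values[k, j], rel=1e-9, abs=1e-15)

    def test_built_twice_is_bit_identical(self, synthetic_thresholded, synthetic_layout):
        a = build_brick_plot(synthetic_thresholded, synthetic_layout, "C05")
        b = build_brick_plot(synthetic_thresholded, synthetic_layout, "C05")
        assert plot_to_json(a) == plot_to_json(b)

    def test_json_round_trip(self, synthetic_thresholded, synthetic_layout):
        plot = build_brick_plot(synthetic_thresholded, synthetic_layout, "C03")
        again = plot_from_json(plot_to_json(plot))
        assert plot_to_json(again) == plot_to_json(plot)

    def test_per_marker_scale_mode(self, synthetic_thresholded, synthetic_layout):
        cfg = GeometryConfig(scale_mode="per_marker")
        plot = build_brick_plot(
            synthetic_thresholded, synthetic_layout, "C01", cfg
        )
        values = np.asarray(synthetic_thresholded.values)
        col_max = values.max(axis=0)
        j = int(np.argmax(values[0] / np.where(col_max > 0, col_max, 1.0)))
        expected = plot.scale_factor * values[0, j] / col_max[j]
        assert plot.bricks[j].area == pytest.approx(expected, rel=1e-12)

    def test_raising_cutoff_never_adds_bricks(self, synthetic_dataset, synthetic_layout):
        counts = []
        for cutoff in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0):
            t = apply_zero_threshold(
                synthetic_dataset.table, ThresholdConfig(zero_cutoff=cutoff)
            )
            if np.max(t.values) == 0.0:
                counts.append(0)
                continue
            plot = build_brick_plot(t, synthetic_layout, "C01")
            counts.append(len(plot.rendered_bricks))
        assert counts == sorted(counts, reverse=True)
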