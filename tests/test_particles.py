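"""Tests for particle measurement and gated analysis."""

import numpy as np
import pytest

from aponecv.particles import (GateParams, analyze_particles, label_components,
                               measure_particle, perimeter_corner_weighted,
                               trace_boundary)

CUT = 2.0 - np.sqrt(2.0)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestLabelComponents:
    def test_empty(self):
        labelled, n = label_components(np.zeros((5, 5), bool))
        assert n == 0 and not labelled.any()

    def test_raster_order(self):
        m = np.zeros((10, 10), bool)
        m[1:3, 6:8] = True   # first foreground pixel in raster order
        m[5:7, 1:3] = True
        labelled, n = label_components(m)
        assert n == 2
        assert labelled[1, 6] == 1 and labelled[5, 1] == 2

    def test_agrees_with_flood_fill_oracle(self, rng):
        m = rng.random((24, 24)) < 0.35
        labelled, n = label_components(m)
        # oracle: 8-connected flood fill from every unvisited fg pixel
        seen = np.zeros_like(m, int)
        comp = 0
        for y in range(24):
            for x in range(24):
                if m[y, x] and not seen[y, x]:
                    comp += 1
                    stack = [(y, x)]
                    while stack:
                        cy, cx = stack.pop()
                        if not (0 <= cy < 24 and 0 <= cx < 24):
                            continue
                        if not m[cy, cx] or seen[cy, cx]:
                            continue
                        seen[cy, cx] = comp
                        stack += [(cy + dy, cx + dx)
                                  for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
        assert n == comp
        for c in range(1, comp + 1):
            labels_here = np.unique(labelled[seen == c])
            assert labels_here.size == 1  # one label per oracle component


class TestMeasureParticle:
    def test_square_closed_forms(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        labelled, _ = label_components(m)
        rec = measure_particle(labelled, 1, np.full((20, 20), 3.0))
        assert rec.area == 100
        # crack polygon 40 minus 4 corner cuts under the traced convention
        assert rec.perimeter == pytest.approx(40 - 4 * CUT)
        assert rec.circularity == pytest.approx(
            4 * np.pi * 100 / (40 - 4 * CUT) ** 2)
        assert rec.mean_intensity == pytest.approx(3.0)
        assert rec.integrated_density == pytest.approx(300.0)
        assert rec.centroid == pytest.approx((10.0, 10.0))
        assert not rec.touches_edge

    def test_rectangle_closed_forms(self):
        m = np.zeros((12, 16), bool)
        m[4:7, 3:10] = True  # 3x7 rectangle
        labelled, _ = label_components(m)
        rec = measure_particle(labelled, 1, np.zeros((12, 16)))
        assert rec.area == 21
        assert rec.perimeter == pytest.approx(20 - 4 * CUT)

    def test_thin_line_scores_below_round_cell_gates(self):
        m = np.zeros((5, 20), bool)
        m[2, 5:15] = True  # 1x10 line
        labelled, _ = label_components(m)
        rec = measure_particle(labelled, 1, np.zeros((5, 20)))
        assert rec.area == 10
        assert rec.perimeter == pytest.approx(22 - 3 * CUT)
        assert rec.circularity < 0.6  # rejected by the strictest gate in use

    def test_disk_circularity_grows_toward_one(self):
        last = 0.0
        for r in (10, 20, 40):
            m = disk_mask((2 * r + 10, 2 * r + 10), r + 5, r + 5, r)
            labelled, _ = label_components(m)
            rec = measure_particle(labelled, 1, np.zeros(m.shape))
            assert 0.85 < rec.circularity <= 1.0
            assert rec.circularity > last
            last = rec.circularity

    def test_include_holes_fills_for_measurement(self):
        yy, xx = np.mgrid[0:21, 0:21]
        d = np.hypot(yy - 10, xx - 10)
        ring = (d <= 8) & (d >= 5)
        labelled, _ = label_components(ring)
        with_holes = measure_particle(labelled, 1, np.zeros((21, 21)),
                                      include_holes=True)
        without = measure_particle(labelled, 1, np.zeros((21, 21)),
                                   include_holes=False)
        assert with_holes.area == disk_mask((21, 21), 10, 10, 8).sum()
        assert without.area == ring.sum()
        assert with_holes.circularity > without.circularity

    def test_missing_label_raises(self):
        labelled, _ = label_components(np.ones((3, 3), bool))
        with pytest.raises(KeyError):
            measure_particle(labelled, 5, np.zeros((3, 3)))


class TestTraceBoundary:
    def test_single_pixel(self):
        # a 1-px crack square is a pure staircase: alternate vertices count
        # as corners, so exactly 2 of its 4 right angles are cut
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert perimeter_corner_weighted(trace_boundary(m)) == pytest.approx(
            4 - 2 * CUT)

    def test_diagonal_staircase_measures_sqrt2(self):
        # 45-degree staircase: n steps should measure ~ n*sqrt(2) per side
        n = 12
        m = np.zeros((n + 2, n + 2), bool)
        for i in range(n):
            m[i + 1, i + 1] = True
        p = perimeter_corner_weighted(trace_boundary(m))
        # closed outline of a 1-px-wide diagonal line: two sqrt(2) sides
        assert p == pytest.approx(2 * n * np.sqrt(2), rel=0.15)


class TestAnalyzeParticles:
    def test_square_passes_validated_gates(self):
        m = np.zeros((30, 30), bool)
        m[10:20, 10:20] = True
        gate = GateParams(size_min=100, size_max=np.inf, circ_min=0.2, circ_max=1)
        records, summary, overlay = analyze_particles(m, gate)
        assert summary.count == 1

    def test_circularity_gate_separates_square_from_line(self):
        m = np.zeros((40, 120), bool)
        m[5:15, 5:15] = True      # square, circ ~ 0.89
        m[25, 5:105] = True       # 1x100 line, circ << 0.6
        gate = GateParams(size_min=10, size_max=np.inf, circ_min=0.6, circ_max=1)
        _, summary, _ = analyze_particles(m, gate)
        assert summary.count == 1

    def test_edge_exclusion_contract(self):
        m = np.zeros((30, 30), bool)
        m[0:10, 10:20] = True  # touches row 0
        gate = GateParams(size_min=10, size_max=np.inf, circ_min=0.0, circ_max=1)
        _, s_excl, _ = analyze_particles(m, gate, exclude_edges=True)
        _, s_incl, _ = analyze_particles(m, gate, exclude_edges=False)
        assert s_excl.count == 0 and s_incl.count == 1

    def test_gate_relaxation_is_monotone(self, rng):
        m = rng.random((64, 64)) < 0.25
        tight = GateParams(size_min=10, size_max=60, circ_min=0.3, circ_max=0.9)
        loose = GateParams(size_min=5, size_max=np.inf, circ_min=0.1, circ_max=1)
        _, s_tight, _ = analyze_particles(m, tight, exclude_edges=False)
        _, s_loose, _ = analyze_particles(m, loose, exclude_edges=False)
        assert s_loose.count >= s_tight.count

    def test_summary_conservation(self, rng):
        m = rng.random((48, 48)) < 0.3
        gate = GateParams(size_min=3, size_max=np.inf, circ_min=0.0, circ_max=1)
        ref = rng.uniform(0, 100, (48, 48))
        records, summary, _ = analyze_particles(m, gate, exclude_edges=False,
                                                reference=ref)
        accepted = [r for r in records if r.accepted]
        assert summary.count == len(accepted)
        assert summary.total_area == pytest.approx(
            sum(r.area for r in accepted))
        assert summary.percent_area == pytest.approx(
            100 * summary.total_area / m.size)
        if accepted:
            assert summary.average_size * summary.count == pytest.approx(
                summary.total_area)

    def test_overlay_colours_accepted_and_whites_rejected(self):
        m = np.zeros((40, 40), bool)
        m[5:15, 5:15] = True     # accepted
        m[25:27, 25:27] = True   # too small -> white
        gate = GateParams(size_min=50, size_max=np.inf, circ_min=0.0, circ_max=1)
        records, summary, overlay = analyze_particles(m, gate)
        assert summary.count == 1
        assert (overlay[25:27, 25:27] == 255).all()
        accepted_px = overlay[8, 8]
        assert not (accepted_px == 255).all() and accepted_px.any()
        numbers = [r.number for r in records if r.accepted]
        assert numbers == [1]

    def test_shape_mismatch_raises(self):
        gate = GateParams(size_min=0, size_max=np.inf, circ_min=0, circ_max=1)
        with pytest.raises(ValueError):
            analyze_particles(np.zeros((5, 5), bool), gate,
                              reference=np.zeros((6, 6)))
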