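"""Detection threshold/footprint rules, colocalization, rasters, durations."""

import numpy as np
import pandas as pd
import pytest

from rfbsim.foci import (
    DetectionParams,
    FocusCall,
    build_rasters,
    colocalize,
    detect_foci,
    duration_bounds,
    summarize_rasters,
)
from rfbsim.microscopy import ImagingParams

SHAPE = (8, 24, 24)  # (Z, Y, X)
BG = 100.0


def volume_with_spots(spots, bg=BG, shape=SHAPE):
    """Flat background plus 3D Gaussian spots: (z, y, x, amplitude, sigma)."""
    vol = np.full(shape, bg)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    for z, y, x, amp, sigma in spots:
        vol += amp * np.exp(
            -((zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2)
        )
    return vol


def full_mask(shape=SHAPE):
    return np.ones(shape, dtype=bool)


def call_with_voxels(voxels):
    voxels = frozenset(voxels)
    zs, ys, xs = zip(*voxels)
    centroid = (float(np.mean(zs)), float(np.mean(ys)), float(np.mean(xs)))
    return FocusCall(voxels, centroid, 1.0, float(len(voxels)))


class TestDetectFoci:
    def test_flat_background_no_calls(self):
        assert detect_foci(volume_with_spots([]), full_mask()) == []

    def test_single_bright_spot_one_call(self):
        vol = volume_with_spots([(4, 12, 12, 10 * BG, 1.5)])
        calls = detect_foci(vol, full_mask())
        assert len(calls) == 1
        z, y, x = calls[0].centroid
        assert (z, y, x) == pytest.approx((4, 12, 12), abs=0.2)
        assert calls[0].peak > 3 * BG

    def test_dim_spot_below_threshold_rejected(self):
        # peak 2x background at k = 3: never crosses the threshold
        vol = volume_with_spots([(4, 12, 12, 1.0 * BG, 1.5)])  # peak = 2x bg
        assert detect_foci(vol, full_mask(), DetectionParams(k=3)) == []

    def test_footprint_rule_rejects_single_pixel_column(self):
        # a bright 1x1 in-plane column has no 2x2 cross-section
        vol = np.full(SHAPE, BG)
        vol[3:6, 12, 12] = 10 * BG
        assert detect_foci(vol, full_mask()) == []
        # widen to 2x2 in one plane: accepted
        vol[4, 12:14, 12:14] = 10 * BG
        assert len(detect_foci(vol, full_mask())) == 1

    def test_lowering_k_never_loses_calls(self):
        rng = np.random.default_rng(0)
        spots = [
            (int(rng.integers(2, 6)), int(rng.integers(4, 20)),
             int(rng.integers(4, 20)), float(rng.uniform(2, 8)) * BG, 1.5)
            for _ in range(4)
        ]
        vol = volume_with_spots(spots)
        n5 = len(detect_foci(vol, full_mask(), DetectionParams(k=5)))
        n3 = len(detect_foci(vol, full_mask(), DetectionParams(k=3)))
        assert n3 >= n5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            detect_foci(volume_with_spots([]), np.zeros(SHAPE, dtype=bool))

    def test_mask_restricts_detection(self):
        vol = volume_with_spots([(4, 4, 4, 10 * BG, 1.5)])
        mask = np.zeros(SHAPE, dtype=bool)
        mask[:, 12:, 12:] = True  # spot outside mask
        assert detect_foci(vol, mask) == []


class TestColocalize:
    def test_identical_voxel_sets_pair(self):
        a = call_with_voxels({(1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2)})
        assert len(colocalize([a], [a])) == 1

    def test_disjoint_sets_do_not_pair(self):
        a = call_with_voxels({(1, 1, 1), (1, 1, 2)})
        b = call_with_voxels({(5, 5, 5), (5, 5, 6)})
        assert colocalize([a], [b]) == []

    def test_two_voxel_overlap_pairs_one_does_not(self):
        a = call_with_voxels({(1, 1, 1), (1, 1, 2), (1, 1, 3)})
        b2 = call_with_voxels({(1, 1, 2), (1, 1, 3), (1, 1, 4)})  # shares 2
        b1 = call_with_voxels({(1, 1, 3), (1, 1, 4), (1, 1, 5)})  # shares 1
        assert len(colocalize([a], [b2])) == 1
        assert colocalize([a], [b1]) == []

    def test_symmetric_under_channel_swap(self):
        a = call_with_voxels({(1, 1, 1), (1, 1, 2), (1, 1, 3)})
        b = call_with_voxels({(1, 1, 2), (1, 1, 3)})
        ab = colocalize([a], [b])
        ba = colocalize([b], [a])
        assert [(x.voxels, y.voxels) for x, y in ab] == \
               [(y.voxels, x.voxels) for x, y in ba]

    def test_at_most_one_partner_largest_overlap_wins(self):
        a = call_with_voxels({(1, 1, y) for y in range(6)})
        b_small = call_with_voxels({(1, 1, 0), (1, 1, 1)})           # overlap 2
        b_big = call_with_voxels({(1, 1, y) for y in range(2, 6)})   # overlap 4
        pairs = colocalize([a], [b_small, b_big])
        assert len(pairs) == 1
        assert pairs[0][1].voxels == b_big.voxels

    def test_projection_mode_counts_2d_footprints(self):
        # same xy footprint in different z planes: only pairs in 2D mode
        a = call_with_voxels({(1, 5, 5), (1, 5, 6)})
        b = call_with_voxels({(6, 5, 5), (6, 5, 6)})
        assert colocalize([a], [b]) == []
        assert len(colocalize([a], [b], projection=True)) == 1


def flags_frame(cell_id, rad52_frames=(), coloc_frames=(), pcna_frames=(),
                n_frames=19, dt=5.0):
    rows = []
    for k in range(n_frames):
        rows.append({
            "cell_id": cell_id, "frame": k, "time_min": k * dt,
            "has_rad52": k in rad52_frames or k in coloc_frames,
            "colocalized": k in coloc_frames,
            "has_pcna": k in pcna_frames,
        })
    return pd.DataFrame(rows)


def anaphase_frame(entries):
    return pd.DataFrame(
        [{"cell_id": c, "anaphase_min": a, "mask_label": i + 1}
         for i, (c, a) in enumerate(entries)]
    )


class TestBuildRasters:
    imaging = ImagingParams()

    def test_frames_map_to_staged_timepoints(self):
        flags = flags_frame("c1", rad52_frames={4, 5, 6, 7, 8})
        raster = build_rasters(flags, anaphase_frame([("c1", 0.0)]), self.imaging)
        on = raster[raster.has_rad52].timepoint_min.tolist()
        assert on == [20.0, 25.0, 30.0, 35.0, 40.0]
        assert not raster.colocalized.any()

    def test_nonzero_anaphase_shifts_staging(self):
        # anaphase at 5 min: staged t=0 is frame 1, so the cell's 0-90 window
        # needs frames 1..19 -> frame 19 missing -> excluded
        flags = flags_frame("c1")
        raster = build_rasters(flags, anaphase_frame([("c1", 5.0)]), self.imaging)
        assert raster.empty

    def test_incomplete_cells_excluded_complete_kept(self):
        flags = pd.concat([
            flags_frame("ok", coloc_frames={4}),
            flags_frame("late", coloc_frames={4}),
        ])
        ana = anaphase_frame([("ok", 0.0), ("late", 30.0)])
        raster = build_rasters(flags, ana, self.imaging)
        assert set(raster.cell_id) == {"ok"}
        assert len(raster) == 19

    def test_missing_anaphase_time_errors(self):
        flags = flags_frame("c1")
        ana = anaphase_frame([("c1", np.nan)])
        with pytest.raises(ValueError, match="anaphase"):
            build_rasters(flags, ana, self.imaging)


class TestSummarizeRasters:
    imaging = ImagingParams()

    def _raster(self, specs):
        flags = pd.concat([flags_frame(c, **kw) for c, kw in specs])
        ana = anaphase_frame([(c, 0.0) for c, _ in specs])
        return build_rasters(flags, ana, self.imaging)

    def test_all_false_rasters(self):
        s = summarize_rasters(self._raster([("c1", {}), ("c2", {})]))
        assert s.pct_cells_with_rad52 == 0.0
        assert s.pct_cells_colocalizing == 0.0
        assert s.mean_coloc_timepoints_all_cells == 0.0

    def test_single_streak_cell(self):
        s = summarize_rasters(
            self._raster([("c1", {"coloc_frames": {4, 5, 6, 7, 8}})])
        )
        assert s.pct_cells_colocalizing == 100.0
        assert s.mean_coloc_timepoints_coloc_cells == 5.0
        assert s.mean_longest_run_timepoints == 5.0
        assert s.n_cells_with_gaps == 0

    def test_gap_statistics(self):
        s = summarize_rasters(
            self._raster([("c1", {"coloc_frames": {4, 10}})])
        )
        assert s.n_cells_with_gaps == 1
        assert s.max_gap_min == 25.0  # frames 5..9 empty
        assert s.mean_longest_run_timepoints == 1.0

    def test_end_before_pcna_loss(self):
        s = summarize_rasters(self._raster([
            ("before", {"coloc_frames": {4, 5}, "pcna_frames": set(range(3, 12))}),
            ("after", {"coloc_frames": {10, 13}, "pcna_frames": set(range(3, 12))}),
        ]))
        assert s.pct_end_before_pcna_loss == 50.0

    def test_invariant_under_cell_reordering(self):
        specs = [("a", {"coloc_frames": {4, 5}}), ("b", {"rad52_frames": {6}}),
                 ("c", {})]
        s1 = summarize_rasters(self._raster(specs))
        s2 = summarize_rasters(self._raster(specs[::-1]))
        assert s1 == s2

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError):
            summarize_rasters(pd.DataFrame(
                columns=["cell_id", "timepoint_min", "has_rad52",
                         "colocalized", "has_pcna"]))


class TestDurationBounds:
    @pytest.mark.parametrize("n,interval,expected", [
        (3.4, 5.0, (12.0, 17.0)),
        (5.8, 5.0, (24.0, 29.0)),
        (1.0, 5.0, (0.0, 5.0)),
        (9.0, 5.0, (40.0, 45.0)),
    ])
    def test_bounds(self, n, interval, expected):
        assert duration_bounds(n, interval) == pytest.approx(expected)

    def test_width_equals_interval(self):
        lo, hi = duration_bounds(3.7, 4.0)
        assert hi - lo == pytest.approx(4.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            duration_bounds(0.5, 5.0)
        with pytest.raises(ValueError):
            duration_bounds(2.0, 0.0)
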