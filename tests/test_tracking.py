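import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

import larvascreen as ls
from larvascreen import plates, render
from larvascreen.synthetic import dmso_phenotype, simulate_screen
from larvascreen.tracking import (Detection, TrackingError,
                                  WellROI, call_movement, difference_mask,
                                  grid_rois, measure_well, rois_from_csv,
                                  rois_to_csv, select_channel, track_frames,
                                  update_location)

BG = np.full((4, 4, 3), 210, dtype=np.uint8)


class TestSelectChannel:
    @pytest.mark.parametrize("stim,expected", [
        ((255, 0, 0), 0),    # red lines: |45| beats |210|
        ((0, 180, 0), 1),
        ((0, 0, 230), 2),
        ((210, 210, 210), 0),  # background only: tie broken to channel 0
    ])
    def test_channel_choice(self, stim, expected):
        assert select_channel(BG, stim) == expected

    def test_rejects_non_rgb(self):
        with pytest.raises(TrackingError):
            select_channel(np.zeros((4, 4)), (255, 0, 0))


class TestDifferenceMask:
    def test_identical_images_empty(self):
        img = np.arange(25, dtype=np.uint8).reshape(5, 5)
        assert not difference_mask(img, img).any()

    def test_threshold_boundary_inclusive(self):
        prev = np.full((3, 3), 100, dtype=np.uint8)
        for delta, expected in [(39, False), (40, True)]:
            curr = prev.copy()
            curr[1, 1] += delta
            mask = difference_mask(prev, curr, threshold=40)
            assert mask[1, 1] == expected
            assert mask.sum() == int(expected)

    def test_toy_enumeration(self):
        prev = np.zeros((5, 5), dtype=np.uint8)
        curr = prev.copy()
        changed = [(0, 0), (2, 3), (4, 4)]
        for r, c in changed:
            curr[r, c] = 200
        curr[1, 1] = 10  # below threshold
        mask = difference_mask(prev, curr)
        assert sorted(zip(*np.where(mask))) == sorted(changed)

    def test_signed_mode_keeps_darkened_pixels_only(self):
        prev = np.full((2, 2), 210, dtype=np.uint8)
        curr = np.array([[20, 210], [210, 255]], dtype=np.uint8)
        mask = difference_mask(prev, curr, mode="signed")
        assert mask[0, 0] and not mask[1, 1]

    @given(arrays(np.uint8, (6, 6)), arrays(np.uint8, (6, 6)))
    def test_abs_mode_symmetric_in_sign(self, a, b):
        assert np.array_equal(difference_mask(a, b), difference_mask(b, a))

    def test_dimension_mismatch(self):
        with pytest.raises(TrackingError):
            difference_mask(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMeasureWell:
    ROI = WellROI(well_id="P1-A01", center_row=5.0, center_col=5.0, radius_px=5.0)

    def test_empty_roi(self):
        det = measure_well(np.zeros((11, 11), dtype=bool), self.ROI)
        assert det.area_px == 0 and det.centroid is None

    def test_centroid_arithmetic(self):
        roi = WellROI(well_id="w", center_row=3.0, center_col=3.0, radius_px=3.0)
        mask = np.zeros((7, 7), dtype=bool)
        for r, c in [(1, 1), (1, 3), (3, 2)]:
            mask[r, c] = True
        det = measure_well(mask, roi)
        assert det.area_px == 3
        assert det.centroid == pytest.approx((5 / 3, 2.0))

    def test_blob_split_across_rois_counts_own_pixels(self):
        left = WellROI("L", center_row=5, center_col=4, radius_px=3)
        right = WellROI("R", center_row=5, center_col=12, radius_px=3)
        mask = np.zeros((11, 16), dtype=bool)
        mask[5, 3:6] = True   # inside left only
        mask[5, 11:13] = True  # inside right only
        assert measure_well(mask, left).area_px == 3
        assert measure_well(mask, right).area_px == 2

    def test_roi_outside_image(self):
        with pytest.raises(TrackingError):
            measure_well(np.zeros((4, 4), dtype=bool), self.ROI)


class TestMovementAndLocation:
    def test_call_movement_boundaries(self):
        none = Detection(area_px=0, centroid=None)
        assert not call_movement(none, 3)
        assert call_movement(Detection(area_px=3, centroid=(0.0, 0.0)), 3)
        assert not call_movement(Detection(area_px=2, centroid=(0.0, 0.0)), 3)

    def test_up_from_centroid_and_carry_forward(self):
        roi = WellROI("w", center_row=10.0, center_col=10.0, radius_px=8.0)
        above = Detection(area_px=4, centroid=(6.0, 10.0))
        assert update_location(None, above, True, roi) is True
        # no movement: state carried forward, whatever the detection says
        assert update_location(True, Detection(0, None), False, roi) is True
        assert update_location(None, Detection(0, None), False, roi) is None

    def test_centroid_on_boundary_counts_as_lower(self):
        roi = WellROI("w", center_row=10.0, center_col=10.0, radius_px=8.0)
        on_row = Detection(area_px=2, centroid=(10.0, 10.0))
        assert update_location(None, on_row, True, roi) is False

    def test_movement_without_centroid_is_an_error(self):
        roi = WellROI("w", center_row=10.0, center_col=10.0, radius_px=8.0)
        with pytest.raises(TrackingError):
            update_location(None, Detection(0, None), True, roi)


@pytest.fixture(scope="module")
def rendered_plate():
    """A small rendered 96-well fixture with ground truth."""
    sched = ls.default_schedule(frame_interval_s=100.0)  # 6 frames/period
    geometry = ls.WellGeometry(pixels_per_mm=4.0)
    layout = ls.screen_session_layout([f"d{i}" for i in range(80)], plates=(1,))
    pmap = {lab: dmso_phenotype() for lab in layout.labels}
    tracks = simulate_screen(layout, pmap, sched, geometry, seed=21)
    frames = render.render_frames(tracks, geometry, sched, n_frames=14)
    return sched, geometry, tracks, frames


class TestTrackFrames:
    def test_row_count_is_wells_times_frame_pairs(self, rendered_plate):
        sched, geometry, tracks, frames = rendered_plate
        rois = grid_rois(geometry, (1,))
        obs = track_frames(frames, rois, sched)
        assert len(obs) == 96 * (len(frames) - 1)
        with_dummy = track_frames(frames, rois, sched, include_first_frame=True)
        assert len(with_dummy) == 96 * len(frames)

    def test_static_plate_has_no_movement(self, rendered_plate):
        sched, geo, tracks, frames = rendered_plate
        static = np.stack([frames[0]] * 4)
        obs = track_frames(static, grid_rois(geo, (1,)), sched)
        assert not obs["moved"].any()

    def test_roi_order_does_not_matter(self, rendered_plate):
        sched, geometry, tracks, frames = rendered_plate
        rois = grid_rois(geometry, (1,))
        a = track_frames(frames[:6], rois, sched)
        b = track_frames(frames[:6], list(reversed(rois)), sched)
        key = ["well_id", "frame"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_two_frames(self, rendered_plate):
        sched, geometry, tracks, frames = rendered_plate
        with pytest.raises(TrackingError):
            track_frames(frames[:1], grid_rois(geometry, (1,)), sched)

    def test_movement_calls_match_ground_truth(self, rendered_plate):
        sched, geometry, tracks, frames = rendered_plate
        rois = grid_rois(geometry, (1,))
        obs = track_frames(frames, rois, sched).set_index(["well_id", "frame"])
        agree = total = 0
        for t in tracks:
            for f in range(1, len(frames)):
                total += 1
                agree += obs.loc[(t.well_id, f), "moved"] == t.moved[f]
        assert agree / total >= 0.99


class TestGeometryHelpers:
    def test_rois_disjoint(self, geometry):
        rois = grid_rois(geometry, (1,))
        assert len(rois) == 96
        centers = np.array([[r.center_row, r.center_col] for r in rois])
        radius = rois[0].radius_px
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 2 * radius

    def test_roi_csv_round_trip(self, tmp_path, geometry):
        rois = grid_rois(geometry, (1, 2))
        path = tmp_path / "rois.csv"
        rois_to_csv(rois, path)
        assert rois_from_csv(path) == rois


class TestRenderer:
    def test_lines_do_not_trip_the_threshold(self, geometry):
        # consecutive frames without larvae differ only where lines moved,
        # and never by >= 40 in the selected channel
        sched = ls.default_schedule(frame_interval_s=100.0)
        ph = ls.Phenotype(p_move_base=0.0)
        layout = ls.validation_session_layout(["DMSO"] * 12, plates=(1,))
        tracks = simulate_screen(layout, {"DMSO": ph}, sched, geometry, seed=0)
        # frames 36/37 fall inside the red-line periods
        frames = [render.render_frame(tracks, geometry, sched, t) for t in (36, 37)]
        ch = select_channel(frames[1], (255, 0, 0))
        assert ch == 0
        mask = difference_mask(frames[0][:, :, ch], frames[1][:, :, ch], mode="signed")
        assert not mask.any()
        # but the frames do differ where the lines are (below threshold)
        assert (frames[0] != frames[1]).any()

    def test_difference_centroid_tracks_new_blob_when_disjoint(self, geometry):
        # a 10 px vertical displacement exceeds the blob height, so the
        # change mask is the full new ellipse and its centroid matches
        sched = ls.default_schedule(frame_interval_s=100.0)
        geo = ls.WellGeometry(pixels_per_mm=5.0)
        track = ls.simulate_track(ls.Phenotype(p_move_base=0.0), sched, geo, 0)
        track.moved[1] = True
        track.x_mm[1:] = track.x_mm[0]
        track.y_mm[0] = -1.0
        track.y_mm[1:] = 1.0  # 2 mm = 10 px down
        frames = [render.render_frame([track], geo, sched, t) for t in (0, 1)]
        roi = grid_rois(geo, (1,))[0]
        mask = difference_mask(frames[0][:, :, 0], frames[1][:, :, 0], mode="signed")
        det = measure_well(mask, roi)
        cy, cx = plates.well_center_mm(1, "A", 1)
        expected = ((cy + 1.0) * 5.0, (cx + track.x_mm[1]) * 5.0)
        assert det.centroid == pytest.approx(expected, abs=1.0)

    def test_tracks_must_share_frame_count(self, geometry, fast_schedule):
        a = ls.simulate_track(dmso_phenotype(), fast_schedule, geometry, 0)
        b = ls.simulate_track(dmso_phenotype(), fast_schedule, geometry, 1)
        b.moved = b.moved[:-1]
        b.x_mm = b.x_mm[:-1]
        b.y_mm = b.y_mm[:-1]
        with pytest.raises(render.RenderError):
            render.render_frames([a, b], geometry, fast_schedule)
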