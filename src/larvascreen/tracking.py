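"""Image analysis: change detection and per-well larva measurement.

The analysis mirrors the plate-imaging macro: for every pair of consecutive
images it (1) selects the color channel in which the active visual stimulus
and the background have similar intensities, so moving lines disappear from
the analysis; (2) subtracts the two channel images and thresholds the result
at 40 gray levels; (3) measures, inside each well's circular region of
interest, the area and centroid of the changed pixels; and (4) derives per
well whether the larva moved and — after each movement — whether it sits in
the upper half of the well (smaller image rows, as seen on screen).

Two differencing modes are supported. ``"signed"`` (the pipeline default)
keeps pixels that became darker by at least the threshold, i.e. the newly
occupied position of the dark larva; its centroid tracks the larva's new
location. ``"abs"`` thresholds the absolute difference and marks vacated and
newly occupied pixels alike; it is sign-symmetric but its centroid falls
between the old and new positions, and it fires on residual stimulus contrast
at period transitions, so it is offered as a config switch rather than the
default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import plates
from .protocol import BACKGROUND_RGB, Schedule
from .synthetic import WellGeometry

DEFAULT_THRESHOLD = 40
DEFAULT_MIN_AREA_PX = 3


class TrackingError(ValueError):
    """Inconsistent frames, ROIs or detections."""


@dataclass(frozen=True)
class WellROI:
    """Circular region of interest of one well, in pixel coordinates."""

    well_id: str
    center_row: float
    center_col: float
    radius_px: float

    @property
    def upper_half_boundary_row(self) -> float:
        """Row splitting the well horizontally; smaller rows are 'up'."""
        return self.center_row


@dataclass(frozen=True)
class Detection:
    """Changed-pixel measurement inside one ROI."""

    area_px: int
    centroid: Optional[tuple[float, float]]  # (row, col); None when empty

    def __post_init__(self) -> None:
        if (self.area_px == 0) != (self.centroid is None):
            raise TrackingError("centroid must be absent exactly when area is 0")


@dataclass(frozen=True)
class TrackingConfig:
    threshold: int = DEFAULT_THRESHOLD
    min_area_px: int = DEFAULT_MIN_AREA_PX
    diff_mode: str = "signed"  # "signed" or "abs"


def select_channel(frame_rgb: np.ndarray, stimulus_rgb: Sequence[int],
                   background_rgb: Sequence[int] = BACKGROUND_RGB) -> int:
    """Channel where stimulus and background intensities are most alike
    (ties broken toward the lowest channel index)."""
    frame_rgb = np.asarray(frame_rgb)
    if frame_rgb.ndim != 3 or frame_rgb.shape[2] != 3:
        raise TrackingError("expected a 3-channel image")
    diffs = np.abs(np.asarray(stimulus_rgb, dtype=int) - np.asarray(background_rgb, dtype=int))
    return int(np.argmin(diffs))


def difference_mask(prev_channel: np.ndarray, curr_channel: np.ndarray,
                    threshold: int = DEFAULT_THRESHOLD, mode: str = "abs") -> np.ndarray:
    """Thresholded change mask between two single-channel images.

    ``mode="abs"``: ``|curr - prev| >= threshold`` (threshold inclusive).
    ``mode="signed"``: ``prev - curr >= threshold`` — pixels that darkened,
    i.e. the newly occupied position of a dark larva on a light background.
    """
    prev_channel = np.asarray(prev_channel, dtype=np.int16)
    curr_channel = np.asarray(curr_channel, dtype=np.int16)
    if prev_channel.shape != curr_channel.shape:
        raise TrackingError("image dimensions differ")
    if mode == "abs":
        return np.abs(curr_channel - prev_channel) >= threshold
    if mode == "signed":
        return (prev_channel - curr_channel) >= threshold
    raise TrackingError(f"unknown diff mode {mode!r}")


def _roi_pixels(roi: WellROI, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    r0 = int(np.floor(roi.center_row - roi.radius_px))
    r1 = int(np.ceil(roi.center_row + roi.radius_px)) + 1
    c0 = int(np.floor(roi.center_col - roi.radius_px))
    c1 = int(np.ceil(roi.center_col + roi.radius_px)) + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise TrackingError(f"ROI {roi.well_id} outside image bounds")
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - roi.center_row) ** 2 + (cc - roi.center_col) ** 2 <= roi.radius_px ** 2
    return rr[inside], cc[inside]


def measure_well(mask: np.ndarray, roi: WellROI) -> Detection:
    """Area and centroid of set mask pixels inside the ROI circle."""
    rr, cc = _roi_pixels(roi, mask.shape)
    sel = mask[rr, cc]
    area = int(sel.sum())
    if area == 0:
        return Detection(area_px=0, centroid=None)
    return Detection(area_px=area,
                     centroid=(float(rr[sel].mean()), float(cc[sel].mean())))


def call_movement(det: Detection, min_area_px: int = DEFAULT_MIN_AREA_PX) -> bool:
    """A larva moved when at least ``min_area_px`` pixels changed (inclusive)."""
    if min_area_px < 1:
        raise TrackingError("min_area_px must be >= 1")
    return det.area_px >= min_area_px


def update_location(prev_up: Optional[bool], det: Detection, moved: bool,
                    roi: WellROI) -> Optional[bool]:
    """Upper-half state after this frame: re-evaluated at movements from the
    detection centroid (strictly above the boundary row counts as up), carried
    forward otherwise; None until the first movement."""
    if not moved:
        return prev_up
    if det.centroid is None:
        raise TrackingError("movement called without a centroid")
    return det.centroid[0] < roi.upper_half_boundary_row


def grid_rois(geometry: WellGeometry, plate_ids: Iterable[int] = (1,)) -> list[WellROI]:
    """ROIs of all wells of the given plates on the imaging stage."""
    ppm = geometry.pixels_per_mm
    rois = []
    for addr in plates.iter_wells(plate_ids):
        cy, cx = plates.well_center_mm(*addr)
        rois.append(WellROI(well_id=plates.well_id(*addr), center_row=cy * ppm,
                            center_col=cx * ppm,
                            radius_px=geometry.well_radius_mm * ppm))
    return rois


def rois_to_csv(rois: Sequence[WellROI], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well_id", "center_row", "center_col", "radius_px"])
        for roi in rois:
            writer.writerow([roi.well_id, roi.center_row, roi.center_col, roi.radius_px])


def rois_from_csv(path) -> list[WellROI]:
    with open(path, newline="") as fh:
        return [WellROI(well_id=rec["well_id"], center_row=float(rec["center_row"]),
                        center_col=float(rec["center_col"]),
                        radius_px=float(rec["radius_px"]))
                for rec in csv.DictReader(fh)]


def track_frames(frames: Iterable[np.ndarray], rois: Sequence[WellROI],
                 schedule: Schedule, config: TrackingConfig = TrackingConfig(),
                 include_first_frame: bool = False) -> pd.DataFrame:
    """Observations for every well and consecutive frame pair.

    ``frames`` is any iterable of RGB uint8 images (an array stack or a lazy
    generator); at most ``schedule.total_frames`` are consumed. Returns one
    row per well per frame pair — columns ``well_id``, ``frame`` (the index of
    the later image), ``period``, ``area_px``, ``centroid_row``,
    ``centroid_col``, ``moved``, ``up`` (1.0/0.0/NaN). With
    ``include_first_frame`` a moved=False dummy row per well is emitted for
    frame 0, matching results files that book one row per image rather than
    per image pair.
    """
    frame_periods = schedule.frame_period_index()
    roi_pixels: Optional[list] = None
    up_state: dict[str, Optional[bool]] = {r.well_id: None for r in rois}
    rows: list[dict] = []
    prev: Optional[np.ndarray] = None
    n_seen = 0

    for t, frame in enumerate(frames):
        n_seen = t + 1
        frame = np.asarray(frame)
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise TrackingError("frames must be RGB")
        if t >= schedule.total_frames:
            raise TrackingError("more frames than the schedule defines")
        if roi_pixels is None:
            roi_pixels = [_roi_pixels(r, frame.shape[:2]) for r in rois]
        if t == 0:
            if include_first_frame:
                for roi in rois:
                    rows.append({"well_id": roi.well_id, "frame": 0,
                                 "period": int(frame_periods[0]), "area_px": 0,
                                 "centroid_row": np.nan, "centroid_col": np.nan,
                                 "moved": False, "up": np.nan})
            prev = frame
            continue

        period = schedule.period(int(frame_periods[t]))
        stim_rgb = period.visual.color_rgb if period.visual is not None else BACKGROUND_RGB
        ch = select_channel(frame, stim_rgb)
        mask = difference_mask(prev[:, :, ch], frame[:, :, ch],
                               threshold=config.threshold, mode=config.diff_mode)
        for roi, (rr, cc) in zip(rois, roi_pixels):
            sel = mask[rr, cc]
            area = int(sel.sum())
            det = (Detection(area_px=area, centroid=(float(rr[sel].mean()),
                                                     float(cc[sel].mean())))
                   if area else Detection(area_px=0, centroid=None))
            moved = call_movement(det, config.min_area_px)
            up = update_location(up_state[roi.well_id], det, moved, roi)
            up_state[roi.well_id] = up
            rows.append({"well_id": roi.well_id, "frame": t, "period": period.index,
                         "area_px": area,
                         "centroid_row": det.centroid[0] if det.centroid else np.nan,
                         "centroid_col": det.centroid[1] if det.centroid else np.nan,
                         "moved": moved,
                         "up": float(up) if up is not None else np.nan})
        prev = frame

    if n_seen < 2:
        raise TrackingError("need at least two frames")
    return pd.DataFrame(rows)
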