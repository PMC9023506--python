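"""Rendering of synthetic plate-image sequences.

Frames emulate the acquired images: a light gray background (210, 210, 210),
horizontal stimulus lines of the active period's color composited at partial
opacity (the projector shines through the opaque plate bottom, which diffuses
the pattern), and each larva as a dark horizontal ellipse at its track
position inside its well. The line phase advances by the scheduled speed and
direction between frames.

The larva gray level (default 20) and the line opacity (default 0.7) are
chosen as a contrast budget: any pixel newly covered by a larva darkens by at
least 40 gray levels in every color channel — also where a stimulus line used
to be — while moving lines never change the channel selected for analysis by
40 or more. The image-analysis threshold of 40 therefore separates larval
movement from stimulus motion exactly.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from . import plates
from .protocol import BACKGROUND_RGB, Schedule
from .synthetic import LarvaTrack, WellGeometry


class RenderError(ValueError):
    """Geometry unsuitable for rendering."""


def stage_shape_px(geometry: WellGeometry, plate_ids: Sequence[int]) -> tuple[int, int]:
    h_mm, w_mm = plates.stage_size_mm(plate_ids)
    return (int(np.ceil(h_mm * geometry.pixels_per_mm)),
            int(np.ceil(w_mm * geometry.pixels_per_mm)))


def _plates_of(tracks: Sequence[LarvaTrack]) -> list[int]:
    ids = sorted({(t.address or plates.parse_well_id(t.well_id))[0] for t in tracks})
    return ids


def line_rows_mask(n_rows: int, geometry: WellGeometry, schedule: Schedule,
                   frame_index: int) -> Optional[np.ndarray]:
    """Boolean mask of image rows covered by a stimulus line at this frame,
    or None outside visual periods."""
    period = schedule.frame_period_index()[frame_index]
    p = schedule.period(int(period))
    if p.visual is None:
        return None
    v = p.visual
    t_s = frame_index * schedule.frame_interval_s
    phase = (v.direction_sign * v.speed_mm_per_s * t_s) % v.line_spacing_mm
    row_mm = (np.arange(n_rows) + 0.5) / geometry.pixels_per_mm
    return ((row_mm - phase) % v.line_spacing_mm) < v.line_thickness_mm


def render_frame(tracks: Sequence[LarvaTrack], geometry: WellGeometry,
                 schedule: Schedule, frame_index: int,
                 shape: Optional[tuple[int, int]] = None) -> np.ndarray:
    """One RGB uint8 frame of the plate stage at ``frame_index``."""
    if shape is None:
        shape = stage_shape_px(geometry, _plates_of(tracks))
    img = np.empty((*shape, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB

    rows = line_rows_mask(shape[0], geometry, schedule, frame_index)
    if rows is not None:
        color = np.asarray(schedule.period(
            int(schedule.frame_period_index()[frame_index])).visual.color_rgb, dtype=float)
        alpha = geometry.line_opacity
        img[rows] = alpha * color + (1.0 - alpha) * np.asarray(BACKGROUND_RGB, dtype=float)

    ppm = geometry.pixels_per_mm
    r_radius = geometry.larva_width_mm / 2.0 * ppm
    c_radius = geometry.larva_length_mm / 2.0 * ppm
    if r_radius < 1.0 or c_radius < 1.0:
        raise RenderError("resolution too low to draw a larva")
    for track in tracks:
        addr = track.address or plates.parse_well_id(track.well_id)
        cy, cx = plates.well_center_mm(*addr)
        rr, cc = draw_ellipse((cy + track.y_mm[frame_index]) * ppm,
                              (cx + track.x_mm[frame_index]) * ppm,
                              r_radius, c_radius, shape=shape)
        img[rr, cc] = geometry.larva_intensity
    return np.round(img).astype(np.uint8)


def iter_rendered_frames(tracks: Sequence[LarvaTrack], geometry: WellGeometry,
                         schedule: Schedule,
                         n_frames: Optional[int] = None) -> Iterator[np.ndarray]:
    """Lazily render the frame sequence (memory stays one frame deep)."""
    if not tracks:
        raise RenderError("no tracks to render")
    counts = {t.n_frames for t in tracks}
    if len(counts) != 1:
        raise RenderError("tracks must share a frame count")
    total = min(counts.pop(), n_frames or 10 ** 9)
    shape = stage_shape_px(geometry, _plates_of(tracks))
    for t in range(total):
        yield render_frame(tracks, geometry, schedule, t, shape=shape)


def render_frames(tracks: Sequence[LarvaTrack], geometry: WellGeometry,
                  schedule: Schedule, n_frames: Optional[int] = None) -> np.ndarray:
    """Full (T, H, W, 3) uint8 stack; prefer :func:`iter_rendered_frames`
    for long sequences."""
    return np.stack(list(iter_rendered_frames(tracks, geometry, schedule, n_frames)))


def write_frames(frames: Iterable[np.ndarray], directory, prefix: str = "frame") -> list:
    """Write frames as zero-padded PNGs; returns the paths."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def read_frames(directory, pattern: str = "*.png") -> Iterator[np.ndarray]:
    """Read a PNG frame series back in filename order."""
    import imageio.v3 as iio
    from pathlib import Path

    for path in sorted(Path(directory).glob(pattern)):
        yield iio.imread(path)
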