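"""Stimulus protocol for the 3-h multiwell behavioral assay.

The assay divides a 3-h recording into eighteen 10-min periods. Periods 1-6
and 15 have no stimuli (baseline activity), periods 7-14 show moving-line
visual stimuli (red, green, blue, and fast red; each color first moving down,
then up, in consecutive periods), and periods 16-18 deliver acoustic pulses
(20-s, 1-s, and again 20-s inter-pulse intervals). Frames are captured every
6 s by default, giving 100 frames per period and 1800 frames in total.

Frames are 0-based; periods are 1-based, so period indices can be quoted
directly against the assay description ("period 15", "period 17", ...).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import yaml

#: light gray projection background
BACKGROUND_RGB = (210, 210, 210)
#: line colors, chosen for channel separation against the gray background
RED_RGB = (255, 0, 0)
GREEN_RGB = (0, 180, 0)
BLUE_RGB = (0, 0, 230)

#: standard moving lines: 1 mm thick, 7 mm apart, moving 7 mm per 8 s
STANDARD_SPEED_MM_S = 7.0 / 8.0
#: fast red lines move 7 mm per 0.5 s (16x the standard speed)
FAST_SPEED_MM_S = 7.0 / 0.5
LINE_THICKNESS_MM = 1.0
LINE_SPACING_MM = 7.0

PERIOD_DURATION_S = 600.0
N_PERIODS = 18
DEFAULT_FRAME_INTERVAL_S = 6.0

#: visual stimulus classes in presentation order, with their (down, up) periods
OMR_PERIOD_PAIRS: dict[str, tuple[int, int]] = {
    "red": (7, 8),
    "green": (9, 10),
    "blue": (11, 12),
    "fast_red": (13, 14),
}
VISUAL_CLASSES = tuple(OMR_PERIOD_PAIRS)


class ProtocolError(ValueError):
    """Invalid stimulus or schedule parameters."""


@dataclass(frozen=True)
class VisualStimulus:
    """Moving-line visual stimulus projected through the plate bottom."""

    color_rgb: tuple[int, int, int]
    direction: str  # "down" or "up"
    speed_mm_per_s: float
    line_thickness_mm: float = LINE_THICKNESS_MM
    line_spacing_mm: float = LINE_SPACING_MM
    stimulus_class: str = ""  # "red", "green", "blue" or "fast_red"

    def __post_init__(self) -> None:
        if self.direction not in ("down", "up"):
            raise ProtocolError(f"direction must be 'down' or 'up', got {self.direction!r}")
        if not (self.speed_mm_per_s > 0 and self.line_thickness_mm > 0 and self.line_spacing_mm > 0):
            raise ProtocolError("visual stimulus speed/thickness/spacing must be positive")

    @property
    def direction_sign(self) -> int:
        """+1 for lines moving down (increasing image row), -1 for up."""
        return 1 if self.direction == "down" else -1


@dataclass(frozen=True)
class AcousticStimulus:
    """Repeated sine-wave pulse train (100 ms, 400 Hz by default)."""

    pulse_interval_s: float
    pulse_duration_ms: float = 100.0
    frequency_hz: float = 400.0

    def __post_init__(self) -> None:
        if self.pulse_interval_s <= 0:
            raise ProtocolError("pulse interval must be positive")


@dataclass(frozen=True)
class Period:
    """One 10-min block of the schedule; at most one stimulus modality."""

    index: int  # 1-based
    n_frames: int
    visual: Optional[VisualStimulus] = None
    acoustic: Optional[AcousticStimulus] = None

    def __post_init__(self) -> None:
        if self.visual is not None and self.acoustic is not None:
            raise ProtocolError("a period never has both visual and acoustic stimuli")
        if self.n_frames <= 0:
            raise ProtocolError("n_frames must be positive")


@dataclass(frozen=True)
class Schedule:
    """Ordered list of periods plus the frame capture interval."""

    periods: tuple[Period, ...]
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    @property
    def total_frames(self) -> int:
        return sum(p.n_frames for p in self.periods)

    @property
    def period_starts(self) -> np.ndarray:
        """0-based first frame of each period."""
        n = np.array([p.n_frames for p in self.periods])
        return np.concatenate([[0], np.cumsum(n)[:-1]])

    def frame_period_index(self) -> np.ndarray:
        """1-based period index for every frame (length = total_frames)."""
        return np.repeat([p.index for p in self.periods],
                         [p.n_frames for p in self.periods])

    def period(self, index: int) -> Period:
        """Period by its 1-based index."""
        if not 1 <= index <= len(self.periods):
            raise ProtocolError(f"period index {index} out of range 1..{len(self.periods)}")
        return self.periods[index - 1]

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        out = {"frame_interval_s": self.frame_interval_s, "periods": []}
        for p in self.periods:
            d: dict = {"index": p.index, "n_frames": p.n_frames}
            if p.visual is not None:
                d["visual"] = asdict(p.visual)
                d["visual"]["color_rgb"] = list(p.visual.color_rgb)
            if p.acoustic is not None:
                d["acoustic"] = asdict(p.acoustic)
            out["periods"].append(d)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "Schedule":
        periods = []
        for d in data["periods"]:
            visual = acoustic = None
            if "visual" in d and d["visual"] is not None:
                v = dict(d["visual"])
                v["color_rgb"] = tuple(v["color_rgb"])
                visual = VisualStimulus(**v)
            if "acoustic" in d and d["acoustic"] is not None:
                acoustic = AcousticStimulus(**d["acoustic"])
            periods.append(Period(index=int(d["index"]), n_frames=int(d["n_frames"]),
                                  visual=visual, acoustic=acoustic))
        return cls(periods=tuple(periods), frame_interval_s=float(data["frame_interval_s"]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Schedule":
        return cls.from_dict(yaml.safe_load(text))


def default_schedule(frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> Schedule:
    """The standard 18-period schedule.

    The period length in frames is derived as 600 s / ``frame_interval_s``,
    so reduced-scale schedules (e.g. 10 frames per period at a 60-s interval)
    exercise the same protocol structure quickly.
    """
    n_frames = int(round(PERIOD_DURATION_S / frame_interval_s))
    if n_frames < 2:
        raise ProtocolError("frame interval too long: fewer than 2 frames per period")

    colors = {"red": RED_RGB, "green": GREEN_RGB, "blue": BLUE_RGB, "fast_red": RED_RGB}
    speeds = {"red": STANDARD_SPEED_MM_S, "green": STANDARD_SPEED_MM_S,
              "blue": STANDARD_SPEED_MM_S, "fast_red": FAST_SPEED_MM_S}

    periods: list[Period] = []
    for i in range(1, 7):  # first hour: no stimuli
        periods.append(Period(index=i, n_frames=n_frames))
    for cls_name in VISUAL_CLASSES:  # 80 min of moving lines, down then up
        down, up = OMR_PERIOD_PAIRS[cls_name]
        for index, direction in ((down, "down"), (up, "up")):
            periods.append(Period(
                index=index, n_frames=n_frames,
                visual=VisualStimulus(color_rgb=colors[cls_name], direction=direction,
                                      speed_mm_per_s=speeds[cls_name],
                                      stimulus_class=cls_name)))
    periods.append(Period(index=15, n_frames=n_frames))  # rest period
    for index, interval in ((16, 20.0), (17, 1.0), (18, 20.0)):
        periods.append(Period(index=index, n_frames=n_frames,
                              acoustic=AcousticStimulus(pulse_interval_s=interval)))
    return Schedule(periods=tuple(periods), frame_interval_s=frame_interval_s)


def period_of_frame(schedule: Schedule, frame_index: int) -> Period:
    """Period containing a 0-based frame index."""
    if not 0 <= frame_index < schedule.total_frames:
        raise ProtocolError(
            f"frame index {frame_index} out of range 0..{schedule.total_frames - 1}")
    start = 0
    for p in schedule.periods:
        if frame_index < start + p.n_frames:
            return p
        start += p.n_frames
    raise AssertionError("unreachable: frames partition into periods")


def stimulus_speed_ratio(fast: VisualStimulus, standard: VisualStimulus) -> float:
    """Ratio of two line speeds (16 for fast red vs standard lines)."""
    return fast.speed_mm_per_s / standard.speed_mm_per_s
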