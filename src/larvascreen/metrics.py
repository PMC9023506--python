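"""Per-larva outcome measures from frame-level observations.

Each larva's recording is reduced to eighteen 10-min period summaries
(percentage of frames with movement, percentage of time in the upper half of
the well) and then to the ten primary outcome measures:

==========  =====================================================================
``act_1h``  1 h: mean activity over periods 1-6 (no stimuli), in % of frames
``act_p15`` P15: activity in period 15 (no stimuli), in %
``hab``     Hab: first minus second 5 min of period 17 activity, in % points
``startle`` S: period 16 minus period 15 activity (20-s acoustic pulses), pp
``excit``   E: period 17 minus period 16 activity (1-s acoustic pulses), pp
``omr_*``   R/G/B/FR: % up in the up-moving minus the down-moving period of the
            red/green/blue/fast-red line pair, pp
``omr_rgb`` RGB: combined optomotor response over all line classes, pp
==========  =====================================================================

Exclusion rules are applied exactly as in the data-processing templates:
larvae moving in less than 1% of all frames are excluded entirely; a period in
which a larva moves less than 5% of the time is excluded from optomotor
measurements using that period.

The ``up`` state of a larva is evaluated after each movement (is the detection
centroid in the upper half of the well?) and carried forward between
movements; it is undefined before the first movement. ``%up`` is therefore a
time fraction over the frames where the state is defined. An events-only
variant (``up_mode="events"``) counts only movement frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import OMR_PERIOD_PAIRS, Schedule

#: measure keys in canonical column order
MEASURES = ["act_1h", "act_p15", "hab", "startle", "excit",
            "omr_red", "omr_green", "omr_blue", "omr_fast_red", "omr_rgb"]
#: short display names used in figures and exported tables
DISPLAY_NAMES = {"act_1h": "1h", "act_p15": "P15", "hab": "Hab", "startle": "S",
                 "excit": "E", "omr_red": "R", "omr_green": "G", "omr_blue": "B",
                 "omr_fast_red": "FR", "omr_rgb": "RGB"}
#: the five optomotor measures (down-weighted in clustering)
OMR_MEASURES = MEASURES[5:]
ACTIVITY_MEASURES = MEASURES[:5]

TOTAL_EXCLUSION_PCT = 1.0
OMR_MIN_MOVE_PCT = 5.0


class MetricsError(ValueError):
    """Observations inconsistent with the schedule or exclusion contract."""


@dataclass
class PeriodSummary:
    period: int
    pct_move: float
    pct_up: float  # nan when the up state was never defined in the period
    n_frames: int
    n_frames_defined_up: int
    first_half_pct_move: float = float("nan")  # populated for period 17
    second_half_pct_move: float = float("nan")


@dataclass
class ExclusionFlags:
    excluded_total: bool
    omr_period_invalid: set[int] = field(default_factory=set)


@dataclass
class BehaviorVector:
    """The ten outcome measures; undefined components are nan."""

    act_1h: float
    act_p15: float
    hab: float
    startle: float
    excit: float
    omr_red: float
    omr_green: float
    omr_blue: float
    omr_fast_red: float
    omr_rgb: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MEASURES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "BehaviorVector":
        return cls(**dict(zip(MEASURES, map(float, values))))


def _pct(count: int, total: int) -> float:
    return 100.0 * count / total if total > 0 else float("nan")


def summarize_periods(obs: pd.DataFrame, schedule: Schedule,
                      total_exclusion_pct: float = TOTAL_EXCLUSION_PCT,
                      omr_min_move_pct: float = OMR_MIN_MOVE_PCT,
                      ) -> tuple[list[PeriodSummary], ExclusionFlags]:
    """Period summaries and exclusion flags for one larva.

    ``obs`` holds one row per observed frame with columns ``frame`` (0-based
    global index), ``moved`` (bool) and ``up`` (1.0/0.0/NaN). The first frame
    of a recording has no predecessor image and is normally absent.
    """
    frames = np.asarray(obs["frame"], dtype=int)
    if len(frames) == 0:
        raise MetricsError("no observations")
    if frames.max() >= schedule.total_frames or frames.min() < 0:
        raise MetricsError("observation frames outside the schedule")
    if len(np.unique(frames)) != len(frames):
        raise MetricsError("duplicate frames in observation series")

    moved = np.asarray(obs["moved"], dtype=bool)
    up = np.asarray(obs["up"], dtype=float)

    period_of = schedule.frame_period_index()[frames]
    starts = schedule.period_starts

    summaries: list[PeriodSummary] = []
    invalid: set[int] = set()
    for p in schedule.periods:
        sel = period_of == p.index
        n = int(sel.sum())
        n_moved = int(moved[sel].sum())
        defined = sel & ~np.isnan(up)
        n_def = int(defined.sum())
        n_up = int(np.nansum(up[defined])) if n_def else 0
        summary = PeriodSummary(period=p.index, pct_move=_pct(n_moved, n),
                                pct_up=_pct(n_up, n_def), n_frames=n,
                                n_frames_defined_up=n_def)
        if p.index == 17 and n > 0:
            # halves split 50/50; an odd frame count gives the extra frame
            # to the first half
            split = starts[p.index - 1] + (p.n_frames + 1) // 2
            first = sel & (frames < split)
            second = sel & (frames >= split)
            summary.first_half_pct_move = _pct(int(moved[first].sum()), int(first.sum()))
            summary.second_half_pct_move = _pct(int(moved[second].sum()), int(second.sum()))
        summaries.append(summary)
        if n == 0 or summary.pct_move < omr_min_move_pct:
            invalid.add(p.index)

    overall_pct = _pct(int(moved.sum()), len(moved))
    flags = ExclusionFlags(excluded_total=overall_pct < total_exclusion_pct,
                           omr_period_invalid=invalid)
    return summaries, flags


def omr(up_period: PeriodSummary, down_period: PeriodSummary,
        flags: ExclusionFlags) -> float:
    """Optomotor response of one line class, in percentage points.

    Positive values mean the larva followed the lines (spent more time in the
    upper well half while lines moved up than while they moved down). NaN when
    either period is excluded by the 5% rule or has no defined location.
    """
    if up_period.period == down_period.period:
        raise MetricsError("up/down periods must differ")
    if (up_period.period in flags.omr_period_invalid
            or down_period.period in flags.omr_period_invalid):
        return float("nan")
    return up_period.pct_up - down_period.pct_up


def behavior_vector(summaries: Sequence[PeriodSummary], flags: ExclusionFlags,
                    omr_rgb_mode: str = "mean") -> BehaviorVector:
    """Reduce 18 period summaries to the ten outcome measures.

    ``omr_rgb_mode="mean"`` (default) combines the per-class optomotor
    responses as the unweighted mean of the defined ones; ``"pooled"`` compares
    location pooled across all valid up-moving vs down-moving periods.
    """
    if flags.excluded_total:
        raise MetricsError("larva is excluded (moved <1% of the recording)")
    by_index = {s.period: s for s in summaries}

    act_1h = float(np.mean([by_index[i].pct_move for i in range(1, 7)]))
    act_p15 = by_index[15].pct_move
    hab = by_index[17].first_half_pct_move - by_index[17].second_half_pct_move
    startle = by_index[16].pct_move - by_index[15].pct_move
    excit = by_index[17].pct_move - by_index[16].pct_move

    omrs = {}
    for cls_name, (down_i, up_i) in OMR_PERIOD_PAIRS.items():
        omrs[cls_name] = omr(by_index[up_i], by_index[down_i], flags)

    if omr_rgb_mode == "mean":
        values = [v for v in omrs.values() if not np.isnan(v)]
        omr_rgb = float(np.mean(values)) if values else float("nan")
    elif omr_rgb_mode == "pooled":
        up_n = up_cnt = down_n = down_cnt = 0
        for cls_name, (down_i, up_i) in OMR_PERIOD_PAIRS.items():
            if down_i in flags.omr_period_invalid or up_i in flags.omr_period_invalid:
                continue
            su, sd = by_index[up_i], by_index[down_i]
            up_n += su.n_frames_defined_up
            up_cnt += round(su.pct_up * su.n_frames_defined_up / 100.0)
            down_n += sd.n_frames_defined_up
            down_cnt += round(sd.pct_up * sd.n_frames_defined_up / 100.0)
        omr_rgb = (_pct(up_cnt, up_n) - _pct(down_cnt, down_n)
                   if up_n and down_n else float("nan"))
    else:
        raise MetricsError(f"unknown omr_rgb_mode {omr_rgb_mode!r}")

    return BehaviorVector(act_1h=act_1h, act_p15=act_p15, hab=hab,
                          startle=startle, excit=excit,
                          omr_red=omrs["red"], omr_green=omrs["green"],
                          omr_blue=omrs["blue"], omr_fast_red=omrs["fast_red"],
                          omr_rgb=omr_rgb)


# ---------------------------------------------------------------------------
# batch path: many larvae at once (used for simulated screens)
# ---------------------------------------------------------------------------

def batch_vectors(moved: np.ndarray, up: np.ndarray, frames: np.ndarray,
                  schedule: Schedule,
                  total_exclusion_pct: float = TOTAL_EXCLUSION_PCT,
                  omr_min_move_pct: float = OMR_MIN_MOVE_PCT,
                  omr_rgb_mode: str = "mean",
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized equivalent of summarize_periods + behavior_vector.

    ``moved``: (n_larvae, n_obs) bool; ``up``: same shape, 1.0/0.0/NaN;
    ``frames``: (n_obs,) global frame indices shared by all larvae. Returns
    ``(vectors, excluded)`` where vectors is (n_larvae, 10) with NaN for
    undefined measures and excluded marks larvae failing the 1% rule
    (their vector rows are NaN).
    """
    moved = np.asarray(moved, dtype=bool)
    up = np.asarray(up, dtype=float)
    frames = np.asarray(frames, dtype=int)
    n = moved.shape[0]
    period_of = schedule.frame_period_index()[frames]
    starts = schedule.period_starts

    n_periods = len(schedule.periods)
    pct_move = np.full((n, n_periods), np.nan)
    pct_up = np.full((n, n_periods), np.nan)
    valid = np.zeros((n, n_periods), dtype=bool)

    for j, p in enumerate(schedule.periods):
        sel = period_of == p.index
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        pct_move[:, j] = 100.0 * moved[:, sel].sum(axis=1) / cnt
        defined = ~np.isnan(up[:, sel])
        n_def = defined.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pct_up[:, j] = np.where(
                n_def > 0,
                100.0 * np.nansum(up[:, sel], axis=1) / np.maximum(n_def, 1),
                np.nan)
        valid[:, j] = pct_move[:, j] >= omr_min_move_pct

    p17 = schedule.period(17)
    split = starts[16] + (p17.n_frames + 1) // 2
    sel17 = period_of == 17
    first = sel17 & (frames < split)
    second = sel17 & (frames >= split)
    first_half = 100.0 * moved[:, first].sum(axis=1) / max(int(first.sum()), 1)
    second_half = 100.0 * moved[:, second].sum(axis=1) / max(int(second.sum()), 1)

    excluded = (100.0 * moved.sum(axis=1) / moved.shape[1]) < total_exclusion_pct

    col = {p.index: j for j, p in enumerate(schedule.periods)}
    vectors = np.full((n, len(MEASURES)), np.nan)
    vectors[:, 0] = np.mean(pct_move[:, [col[i] for i in range(1, 7)]], axis=1)
    vectors[:, 1] = pct_move[:, col[15]]
    vectors[:, 2] = first_half - second_half
    vectors[:, 3] = pct_move[:, col[16]] - pct_move[:, col[15]]
    vectors[:, 4] = pct_move[:, col[17]] - pct_move[:, col[16]]

    omr_cols = []
    for k, (cls_name, (down_i, up_i)) in enumerate(OMR_PERIOD_PAIRS.items()):
        val = pct_up[:, col[up_i]] - pct_up[:, col[down_i]]
        val = np.where(valid[:, col[up_i]] & valid[:, col[down_i]], val, np.nan)
        vectors[:, 5 + k] = val
        omr_cols.append(5 + k)
    if omr_rgb_mode == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan rows
            vectors[:, 9] = np.nanmean(vectors[:, omr_cols], axis=1)
    else:  # pooled mode is only offered on the scalar path
        raise MetricsError("batch path supports omr_rgb_mode='mean' only")

    vectors[excluded] = np.nan
    return vectors, excluded


def observations_to_vectors(obs: pd.DataFrame, schedule: Schedule,
                            layout=None, **kwargs) -> pd.DataFrame:
    """Per-larva vector table from a multi-well observation table.

    ``obs`` needs columns ``well_id``, ``frame``, ``moved``, ``up``. Returns
    one row per well with the ten measures, the exclusion flag and (when a
    :class:`~larvascreen.plates.PlateLayout` is given) the treatment label.
    """
    rows = []
    for wid, sub in obs.groupby("well_id", sort=True):
        summaries, flags = summarize_periods(sub, schedule, **{
            k: v for k, v in kwargs.items() if k != "omr_rgb_mode"})
        if flags.excluded_total:
            vec = dict.fromkeys(MEASURES, float("nan"))
        else:
            bv = behavior_vector(summaries, flags,
                                 omr_rgb_mode=kwargs.get("omr_rgb_mode", "mean"))
            vec = {m: getattr(bv, m) for m in MEASURES}
        rows.append({"well_id": wid, "excluded": flags.excluded_total, **vec})
    out = pd.DataFrame(rows)
    if layout is not None:
        from .plates import parse_well_id
        out.insert(1, "label", [layout.wells[parse_well_id(w)] for w in out["well_id"]])
    return out
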