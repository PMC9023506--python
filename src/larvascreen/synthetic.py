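"""Synthetic larval behavior with known ground truth.

The generator produces per-well movement/location time series (and, via
:mod:`larvascreen.render`, plate-image sequences) from a parametric phenotype,
so that every downstream stage — tracking, outcome measures, screen statistics,
clustering — can be tested without any recordings.

The behavior model is a linear-probability model chosen so that expected
outcome measures are closed-form wherever possible:

* per frame, the larva moves with probability
  ``clip(p_move_base + startle_gain * [20-s acoustic period]
  + (startle_gain + excitability_gain) * [1-s acoustic period]
  - habituation_drop * [second half of the 1-s period])``;
* on movement it takes a step of random length and direction inside the well;
  during visual periods the *sign* of the vertical step component is biased
  toward the direction of line motion with probability ``(1 + g)/2`` where
  ``g`` is the optomotor gain of the active line class;
* positions are reflected at a circular boundary inset from the well wall so
  the rendered larva stays inside its well.

Activity-family expectations are exact (e.g. startle gain 0.08 gives an
expected startle measure of 8 percentage points). Optomotor expectations have
no closed form because of the reflecting boundary; they are computed by a
seeded Monte-Carlo oracle (:func:`expected_vector`) and can be inverted with
:func:`calibrate_omr_gain` to program a target optomotor response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics, plates
from .metrics import MEASURES, OMR_MEASURES
from .protocol import Schedule, VISUAL_CLASSES, default_schedule


class PhenotypeError(ValueError):
    """Invalid phenotype parameters."""


def _zero_gains() -> dict[str, float]:
    return {c: 0.0 for c in VISUAL_CLASSES}


@dataclass
class Phenotype:
    """Simulator parameters with a direct mapping to expected behaviors."""

    p_move_base: float
    startle_gain: float = 0.0
    excitability_gain: float = 0.0
    habituation_drop: float = 0.0
    omr_gain: dict[str, float] = field(default_factory=_zero_gains)
    #: swim step length range, mm (uniformly drawn per movement)
    step_min_mm: float = 0.5
    step_max_mm: float = 1.5
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_move_base <= 1.0:
            raise PhenotypeError("p_move_base must be a probability in [0, 1]")
        for name in ("startle_gain", "excitability_gain", "habituation_drop"):
            if not math.isfinite(getattr(self, name)):
                raise PhenotypeError(f"{name} must be finite")
        self.omr_gain = {**_zero_gains(), **self.omr_gain}
        for cls_name, g in self.omr_gain.items():
            if cls_name not in VISUAL_CLASSES:
                raise PhenotypeError(f"unknown stimulus class {cls_name!r}")
            if not -1.0 <= g <= 1.0:
                raise PhenotypeError("omr_gain entries must lie in [-1, 1]")
        if not 0 < self.step_min_mm <= self.step_max_mm:
            raise PhenotypeError("step length range must satisfy 0 < min <= max")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "Phenotype":
        return cls(**dict(data))


@dataclass(frozen=True)
class WellGeometry:
    """Well and larva geometry used by the simulator and renderer."""

    inner_diameter_mm: float = 7.15
    pixels_per_mm: float = 5.0
    larva_length_mm: float = 4.0
    larva_width_mm: float = 1.0
    #: gray level of the rendered larva; dark enough that it differs from the
    #: background and from any composited stimulus line by >= the macro's
    #: threshold of 40
    larva_intensity: int = 20
    #: opacity of stimulus lines projected through the opaque plate bottom
    line_opacity: float = 0.7

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0 or self.pixels_per_mm <= 0:
            raise PhenotypeError("geometry dimensions must be positive")
        if self.position_radius_mm <= 0:
            raise PhenotypeError("larva does not fit in the well")

    @property
    def well_radius_mm(self) -> float:
        return self.inner_diameter_mm / 2.0

    @property
    def position_radius_mm(self) -> float:
        """Maximum distance of the larva center from the well center; keeps
        the rendered body (half its length in any direction) inside the well."""
        return self.well_radius_mm - self.larva_length_mm / 2.0


@dataclass
class LarvaTrack:
    """Per-well ground-truth series: movement flags and positions (mm,
    relative to the well center; y increases downward as in an image, so the
    upper half of the well is y < 0)."""

    well_id: str
    moved: np.ndarray  # (n_frames,) bool; frame 0 is False by convention
    x_mm: np.ndarray
    y_mm: np.ndarray
    ground_truth: Optional[Phenotype] = None
    address: Optional[plates.WellAddress] = None

    @property
    def n_frames(self) -> int:
        return len(self.moved)

    def up_state(self) -> np.ndarray:
        """1.0/0.0 once the larva has moved at least once, NaN before."""
        defined = np.maximum.accumulate(self.moved)
        return np.where(defined, (self.y_mm < 0).astype(float), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"well_id": self.well_id,
                             "frame": np.arange(self.n_frames),
                             "moved": self.moved, "up": self.up_state(),
                             "x_mm": self.x_mm, "y_mm": self.y_mm})


def dmso_phenotype(label: str = "DMSO") -> Phenotype:
    """Baseline (vehicle-control) phenotype.

    Baseline activity of 20% of frames, a 10 pp startle elevation, a further
    15 pp excitability elevation with a 5 pp within-period habituation drop,
    and a uniform optomotor gain of 0.5 — a larva with robust but not
    saturated responses.
    """
    return Phenotype(p_move_base=0.20, startle_gain=0.10, excitability_gain=0.15,
                     habituation_drop=0.05,
                     omr_gain={c: 0.5 for c in VISUAL_CLASSES}, label=label)


# ---------------------------------------------------------------------------
# per-frame parameter tracks
# ---------------------------------------------------------------------------

def frame_move_probability(phenotype: Phenotype, schedule: Schedule) -> np.ndarray:
    """Clipped per-frame movement probability implied by the phenotype."""
    p = np.empty(schedule.total_frames)
    start = 0
    for period in schedule.periods:
        val = phenotype.p_move_base
        if period.acoustic is not None:
            val += phenotype.startle_gain
            if period.acoustic.pulse_interval_s <= 1.0:
                val += phenotype.excitability_gain
                half = (period.n_frames + 1) // 2
                p[start:start + half] = val
                p[start + half:start + period.n_frames] = val - phenotype.habituation_drop
                start += period.n_frames
                continue
        p[start:start + period.n_frames] = val
        start += period.n_frames
    return np.clip(p, 0.0, 1.0)


def frame_omr_bias(phenotype: Phenotype, schedule: Schedule) -> np.ndarray:
    """Per-frame signed vertical bias: omr_gain of the active line class times
    the line direction (+1 down, -1 up); 0 outside visual periods."""
    bias = np.zeros(schedule.total_frames)
    start = 0
    for period in schedule.periods:
        if period.visual is not None:
            g = phenotype.omr_gain.get(period.visual.stimulus_class, 0.0)
            bias[start:start + period.n_frames] = g * period.visual.direction_sign
        start += period.n_frames
    return bias


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

def _simulate_batch(phenotypes: Sequence[Phenotype],
                    seed_seqs: Sequence[np.random.SeedSequence],
                    schedule: Schedule, geometry: WellGeometry,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many wells at once; randomness is drawn per well from its own
    seed sequence, so results are bit-identical however wells are batched."""
    n = len(phenotypes)
    n_frames = schedule.total_frames
    radius = geometry.position_radius_mm

    u_move = np.empty((n, n_frames))
    phi = np.empty((n, n_frames))
    length = np.empty((n, n_frames))
    u_sign = np.empty((n, n_frames))
    x = np.empty((n, n_frames))
    y = np.empty((n, n_frames))

    for i, (ph, ss) in enumerate(zip(phenotypes, seed_seqs)):
        rng = np.random.Generator(np.random.Philox(ss))
        r0 = radius * math.sqrt(rng.random())
        a0 = rng.random() * 2.0 * math.pi
        x[i, 0] = r0 * math.cos(a0)
        y[i, 0] = r0 * math.sin(a0)
        u_move[i] = rng.random(n_frames)
        phi[i] = rng.random(n_frames) * 2.0 * math.pi
        length[i] = rng.uniform(ph.step_min_mm, ph.step_max_mm, n_frames)
        u_sign[i] = rng.random(n_frames)

    # per-frame parameters, cached per distinct phenotype object
    p = np.empty((n, n_frames))
    bias = np.empty((n, n_frames))
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, ph in enumerate(phenotypes):
        key = id(ph)
        if key not in cache:
            cache[key] = (frame_move_probability(ph, schedule),
                          frame_omr_bias(ph, schedule))
        p[i], bias[i] = cache[key]

    moved = np.zeros((n, n_frames), dtype=bool)
    for t in range(1, n_frames):
        m = u_move[:, t] < p[:, t]
        moved[:, t] = m
        # vertical sign biased toward line motion: P(sign matches) = (1+g)/2
        p_down = (1.0 + bias[:, t]) / 2.0
        sign = np.where(u_sign[:, t] < p_down, 1.0, -1.0)
        dx = length[:, t] * np.cos(phi[:, t])
        dy = sign * length[:, t] * np.abs(np.sin(phi[:, t]))
        nx = x[:, t - 1] + dx
        ny = y[:, t - 1] + dy
        r = np.hypot(nx, ny)
        over = r > radius
        if over.any():
            # fold the radius back inside (specular reflection of the radial
            # overshoot); clip guards pathological step lengths
            scale = np.where(over, np.clip(2.0 * radius - r, -radius, radius) / r, 1.0)
            nx = nx * scale
            ny = ny * scale
        x[:, t] = np.where(m, nx, x[:, t - 1])
        y[:, t] = np.where(m, ny, y[:, t - 1])
    return moved, x, y


def well_seed_sequence(seed: int, address: plates.WellAddress) -> np.random.SeedSequence:
    """Stable per-well seed: hash of (master seed, plate, row index, column)."""
    plate, row, col = address
    return np.random.SeedSequence([int(seed), int(plate), plates.ROWS.index(row), int(col)])


def simulate_track(phenotype: Phenotype, schedule: Schedule,
                   geometry: WellGeometry, seed: int,
                   well_id: str = "P1-A01") -> LarvaTrack:
    """Simulate a single larva."""
    moved, x, y = _simulate_batch([phenotype], [np.random.SeedSequence([int(seed)])],
                                  schedule, geometry)
    return LarvaTrack(well_id=well_id, moved=moved[0], x_mm=x[0], y_mm=y[0],
                      ground_truth=phenotype)


def simulate_screen(layout: plates.PlateLayout, phenotype_map: Mapping[str, Phenotype],
                    schedule: Schedule, geometry: WellGeometry, seed: int,
                    ) -> list[LarvaTrack]:
    """One track per well of the layout, reproducible bit-for-bit at a fixed
    master seed regardless of well iteration order."""
    addresses = sorted(layout.wells, key=lambda a: (a[0], plates.ROWS.index(a[1]), a[2]))
    missing = {layout.wells[a] for a in addresses} - set(phenotype_map)
    if missing:
        raise PhenotypeError(f"no phenotype for label(s): {sorted(missing)}")
    phenotypes = [phenotype_map[layout.wells[a]] for a in addresses]
    seqs = [well_seed_sequence(seed, a) for a in addresses]
    moved, x, y = _simulate_batch(phenotypes, seqs, schedule, geometry)
    return [LarvaTrack(well_id=plates.well_id(*a), moved=moved[i], x_mm=x[i],
                       y_mm=y[i], ground_truth=phenotypes[i], address=a)
            for i, a in enumerate(addresses)]


# ---------------------------------------------------------------------------
# tracks -> outcome measures
# ---------------------------------------------------------------------------

def tracks_to_batch(tracks: Sequence[LarvaTrack]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack tracks into (moved, up, frames) arrays for metrics.batch_vectors.
    Frame 0 is dropped: the first image of a recording has no predecessor."""
    moved = np.stack([t.moved for t in tracks])[:, 1:]
    up = np.stack([t.up_state() for t in tracks])[:, 1:]
    frames = np.arange(1, tracks[0].n_frames)
    return moved, up, frames


def vectors_from_tracks(tracks: Sequence[LarvaTrack], schedule: Schedule,
                        layout: Optional[plates.PlateLayout] = None,
                        **kwargs) -> pd.DataFrame:
    """Per-larva vector table (one row per well) straight from tracks."""
    moved, up, frames = tracks_to_batch(tracks)
    vectors, excluded = metrics.batch_vectors(moved, up, frames, schedule, **kwargs)
    out = pd.DataFrame(vectors, columns=MEASURES)
    out.insert(0, "well_id", [t.well_id for t in tracks])
    out.insert(1, "excluded", excluded)
    if layout is not None:
        out.insert(1, "label", [layout.wells[t.address] if t.address is not None
                                else layout.wells[plates.parse_well_id(t.well_id)]
                                for t in tracks])
    elif all(t.ground_truth is not None for t in tracks):
        out.insert(1, "label", [t.ground_truth.label for t in tracks])
    return out


# ---------------------------------------------------------------------------
# expectations and calibration
# ---------------------------------------------------------------------------

def expected_vector(phenotype: Phenotype, schedule: Optional[Schedule] = None,
                    n_mc: int = 2000, seed: int = 0) -> metrics.BehaviorVector:
    """Expected outcome measures under the linear-probability model.

    Activity-family components are closed-form from the clipped per-period
    probabilities. Optomotor components are computed by a seeded Monte-Carlo
    oracle (``n_mc`` simulated larvae) because the reflecting boundary has no
    tractable stationary distribution; with all optomotor gains zero they are
    exactly 0 by symmetry.
    """
    schedule = schedule or default_schedule()
    clip = lambda v: min(max(v, 0.0), 1.0)
    base = clip(phenotype.p_move_base)
    p15 = base
    p16 = clip(phenotype.p_move_base + phenotype.startle_gain)
    p17a = clip(phenotype.p_move_base + phenotype.startle_gain + phenotype.excitability_gain)
    p17b = clip(p17a - phenotype.habituation_drop)
    n17 = schedule.period(17).n_frames
    n17a = (n17 + 1) // 2
    p17 = (n17a * p17a + (n17 - n17a) * p17b) / n17

    omrs = dict.fromkeys(VISUAL_CLASSES, 0.0)
    if any(g != 0.0 for g in phenotype.omr_gain.values()):
        geometry = WellGeometry()
        seqs = [np.random.SeedSequence([int(seed), i]) for i in range(n_mc)]
        moved, x, y = _simulate_batch([phenotype] * n_mc, seqs, schedule, geometry)
        tracks = [LarvaTrack(well_id=f"mc{i}", moved=moved[i], x_mm=x[i], y_mm=y[i])
                  for i in range(n_mc)]
        table = vectors_from_tracks(tracks, schedule)
        for cls_name, col in zip(VISUAL_CLASSES, OMR_MEASURES):
            omrs[cls_name] = float(np.nanmean(table[col]))

    values = [v for v in omrs.values()]
    return metrics.BehaviorVector(
        act_1h=100.0 * base, act_p15=100.0 * p15,
        hab=100.0 * (p17a - p17b), startle=100.0 * (p16 - p15),
        excit=100.0 * (p17 - p16),
        omr_red=omrs["red"], omr_green=omrs["green"], omr_blue=omrs["blue"],
        omr_fast_red=omrs["fast_red"],
        omr_rgb=float(np.mean(values)))


def calibrate_omr_gain(target_pp: float, phenotype: Phenotype,
                       schedule: Optional[Schedule] = None, n_mc: int = 800,
                       seed: int = 0, tol_pp: float = 0.5,
                       max_iter: int = 14) -> float:
    """Uniform optomotor gain whose expected combined optomotor response is
    ``target_pp`` percentage points, found by bisection against the
    Monte-Carlo expectation with common random numbers (the response is
    pathwise monotone in the gain). The gain's sign follows the target's by
    the up/down symmetry of the step model."""
    schedule = schedule or default_schedule()
    magnitude = abs(target_pp)
    if magnitude < 1e-9:
        return 0.0

    def response(g: float) -> float:
        ph = Phenotype(**{**phenotype.to_dict(),
                          "omr_gain": {c: g for c in VISUAL_CLASSES}})
        vec = expected_vector(ph, schedule, n_mc=n_mc, seed=seed)
        return vec.omr_rgb

    lo, hi = 0.0, 1.0
    f_hi = response(hi)
    if f_hi < magnitude:
        raise PhenotypeError(
            f"target optomotor response {target_pp} pp exceeds the model's "
            f"range (+-{f_hi:.1f} pp at unit gain)")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        val = response(mid)
        if abs(val - magnitude) <= tol_pp:
            lo = hi = mid
            break
        if val < magnitude:
            lo = mid
        else:
            hi = mid
    g = (lo + hi) / 2.0
    return math.copysign(g, target_pp)


# ---------------------------------------------------------------------------
# packaged fixture profiles for the clustering demo
# ---------------------------------------------------------------------------

#: sign/magnitude template of a calcineurin-inhibitor-like ("CsA-type")
#: behavioral profile: hyperactivity, raised excitability, suppressed
#: optomotor responses; magnitudes are fixture parameters in pp
CSA_LIKE_DELTAS = {"act_1h": 15.0, "act_p15": 12.0, "hab": 0.0, "startle": 0.0,
                   "excit": 15.0, "omr_red": -15.0, "omr_green": -12.0,
                   "omr_blue": -15.0, "omr_fast_red": -20.0}


def reference_profiles(n_per_family: int = 8, noise_sd: float = 2.0,
                       seed: int = 0) -> pd.DataFrame:
    """Two packaged families of delta profiles with opposite sign patterns.

    ``CsA-like-*`` rows follow :data:`CSA_LIKE_DELTAS`; ``INDY-like-*`` rows
    are their elementwise negation (a DYRK-inhibitor-like profile). Gaussian
    noise of ``noise_sd`` pp is added per component; the combined optomotor
    column is recomputed as the mean of the four noisy per-class responses, so
    rows stay internally consistent. ``noise_sd=0`` gives identical rows
    within each family.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed)])))
    base = np.array([CSA_LIKE_DELTAS[m] for m in MEASURES[:9]])
    rows, labels = [], []
    for family, sign in (("CsA-like", 1.0), ("INDY-like", -1.0)):
        for i in range(n_per_family):
            values = sign * base + noise_sd * rng.standard_normal(9)
            rgb = float(np.mean(values[5:9]))
            rows.append(np.concatenate([values, [rgb]]))
            labels.append(f"{family}-{i + 1:02d}")
    return pd.DataFrame(rows, index=pd.Index(labels, name="label"), columns=MEASURES)
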