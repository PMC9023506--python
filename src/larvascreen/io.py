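"""Plain-text table formats shared by the pipeline stages.

Three tables travel between stages:

* **tracks TSV** — one row per well-frame with the simulator's ground truth
  (``well_id, frame, moved, x_mm, y_mm``);
* **results file** — the 15-column per-image observation dialect of the
  image-analysis stage (image and well identity, larval movement and
  location), accepted by the metrics stage;
* **vectors / profiles TSV** — per-larva outcome measures and per-treatment
  behavioral profiles.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import plates
from .protocol import Schedule
from .synthetic import LarvaTrack

#: the 15 columns of the observation results file
RESULTS_COLUMNS = ["image_index", "image_name", "plate", "well_row", "well_col",
                   "well_id", "period", "frame", "area_px", "centroid_row",
                   "centroid_col", "moved", "up", "x_mm", "y_mm"]


def write_tracks_tsv(tracks: Sequence[LarvaTrack], path) -> None:
    frames = [t.to_frame()[["well_id", "frame", "moved", "x_mm", "y_mm"]]
              for t in tracks]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_tracks_tsv(path) -> list[LarvaTrack]:
    table = pd.read_csv(path, sep="\t")
    out = []
    for wid, sub in table.groupby("well_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(LarvaTrack(well_id=str(wid),
                              moved=sub["moved"].to_numpy(dtype=bool),
                              x_mm=sub["x_mm"].to_numpy(dtype=float),
                              y_mm=sub["y_mm"].to_numpy(dtype=float)))
    return out


def write_results_file(obs: pd.DataFrame, path, schedule: Schedule = None,
                       image_name_fmt: str = "IMG_{frame:05d}.png") -> None:
    """Write observations in the 15-column results dialect.

    ``obs`` is a tracking observation table (or a track's frame table);
    missing measurement columns are left blank.
    """
    out = pd.DataFrame()
    frame = obs["frame"].to_numpy(dtype=int)
    out["image_index"] = frame
    out["image_name"] = [image_name_fmt.format(frame=f) for f in frame]
    addr = [plates.parse_well_id(w) for w in obs["well_id"]]
    out["plate"] = [a[0] for a in addr]
    out["well_row"] = [a[1] for a in addr]
    out["well_col"] = [a[2] for a in addr]
    out["well_id"] = list(obs["well_id"])
    if "period" in obs.columns:
        out["period"] = obs["period"].to_numpy(dtype=int)
    elif schedule is not None:
        out["period"] = schedule.frame_period_index()[frame]
    else:
        out["period"] = -1
    out["frame"] = frame
    for col in ["area_px", "centroid_row", "centroid_col"]:
        out[col] = obs[col].to_numpy() if col in obs.columns else np.nan
    out["moved"] = obs["moved"].to_numpy(dtype=bool).astype(int)
    out["up"] = obs["up"].to_numpy(dtype=float)
    for col in ["x_mm", "y_mm"]:
        out[col] = obs[col].to_numpy(dtype=float) if col in obs.columns else np.nan
    out[RESULTS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results_file(path) -> pd.DataFrame:
    """Read the 15-column dialect back to an observation table."""
    table = pd.read_csv(path, sep="\t")
    missing = set(RESULTS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"results file lacks columns: {sorted(missing)}")
    table["moved"] = table["moved"].astype(bool)
    table["up"] = table["up"].astype(float)
    return table


def write_vectors_tsv(vectors: pd.DataFrame, path) -> None:
    vectors.to_csv(path, sep="\t", index=False)


def read_vectors_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profiles_tsv(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
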