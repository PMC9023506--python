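"""Treatment-level behavioral profiles and screening statistics.

Per-larva vectors are aggregated per treatment group; each group's ten
behaviors are compared to the vehicle (DMSO) control as mean differences in
percentage points, tested two-sided with Welch's unequal-variances t-test,
and flagged against tiered Bonferroni thresholds alpha/m for
alpha in {0.05, 0.01, 0.001} (m = number of treatment-vs-control
comparisons: 190 in the primary screen, 11 in validation experiments, 3 in a
concentration series).

The statistical unit is the larva. Optomotor measures can be undefined for
individual larvae (the 5% period-activity rule), so group n may differ
between behaviors of the same treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import DISPLAY_NAMES, MEASURES

DEFAULT_ALPHAS = (0.05, 0.01, 0.001)
TIER_LABELS = {0: "ns", 1: "*", 2: "**", 3: "***"}


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass
class GroupStats:
    """Per-behavior sample size, mean, sd and sem of one treatment group."""

    label: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    sem: dict[str, float]


@dataclass
class BehavioralProfile:
    """Treatment-vs-control differences (pp) with Welch p-values."""

    label: str
    delta_pp: dict[str, float]
    p_values: dict[str, float]
    n: dict[str, int]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class SignificanceTiers:
    """Tiered Bonferroni thresholds for m comparisons."""

    m: int
    alphas: tuple[float, ...] = DEFAULT_ALPHAS

    def __post_init__(self) -> None:
        if sorted(self.alphas, reverse=True) != list(self.alphas):
            raise StatsError("alphas must be strictly decreasing")

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(bonferroni(a, self.m) for a in self.alphas)

    def classify(self, p: float) -> str:
        """'ns', '*', '**' or '***' (stars = tiers passed)."""
        if np.isnan(p):
            return "ns"
        stars = sum(p < thr for thr in self.thresholds)
        return TIER_LABELS[stars]


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must lie in (0, 1)")
    if m < 1:
        raise StatsError("m must be a positive integer")
    return alpha / m


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances).

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny), with Welch-Satterthwaite
    degrees of freedom. Degenerate zero-variance samples return p = 1 when
    the means agree (p = 0 otherwise) with a warning instead of failing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each sample needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("samples must be finite")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        warnings.warn("zero pooled variance in Welch's test", stacklevel=2)
        if diff == 0.0:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0)
        return WelchResult(t=float(np.copysign(np.inf, diff)),
                           df=float(nx + ny - 2), p=0.0)
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def _welch_from_moments(mx, vx, nx, my, vy, ny):
    """Vectorized Welch test from group moments (means, ddof-1 variances,
    counts). Entries with n < 2 on either side give NaN p."""
    mx, vx, my, vy = (np.asarray(a, dtype=float) for a in (mx, vx, my, vy))
    nx = np.asarray(nx, dtype=float)
    ny = np.asarray(ny, dtype=float)
    valid = (nx >= 2) & (ny >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = vx / nx + vy / ny
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        degenerate = valid & (se2 == 0.0)
        p = np.where(degenerate, np.where(mx == my, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(mx == my, 0.0, np.inf), t)
    p = np.where(valid, p, np.nan)
    return t, df, p


def aggregate(vectors: pd.DataFrame, drop_excluded: bool = True) -> list[GroupStats]:
    """Per-treatment mean/sd/sem/n for each behavior.

    ``vectors`` is the per-larva table (columns ``label`` + the ten measures,
    NaN = undefined). Optomotor n counts only larvae with that measure
    defined; excluded larvae (``excluded`` column) are dropped first.
    """
    if "label" not in vectors.columns:
        raise StatsError("vectors table needs a 'label' column")
    if drop_excluded and "excluded" in vectors.columns:
        vectors = vectors[~vectors["excluded"].astype(bool)]
    out = []
    for label, sub in vectors.groupby("label", sort=True):
        n, mean, sd, sem = {}, {}, {}, {}
        for m in MEASURES:
            vals = sub[m].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            n[m] = len(vals)
            mean[m] = float(vals.mean()) if len(vals) else float("nan")
            sd[m] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            sem[m] = sd[m] / np.sqrt(n[m]) if len(vals) > 1 else float("nan")
        out.append(GroupStats(label=str(label), n=n, mean=mean, sd=sd, sem=sem))
    return out


def profile_screen(vectors: pd.DataFrame, control: str = "DMSO",
                   m: Optional[int] = None,
                   alphas: tuple[float, ...] = DEFAULT_ALPHAS,
                   drop_excluded: bool = True) -> pd.DataFrame:
    """Behavioral profiles of every treatment vs the vehicle control.

    Returns one row per non-control label with columns ``delta_<measure>``
    (treatment mean - control mean, pp), ``p_<measure>`` (two-sided Welch),
    ``n_<measure>`` (treatment n), ``tier_<measure>`` and ``significant``
    (any behavior below the alpha_max/m threshold). ``m`` defaults to the
    number of treatment groups.
    """
    if drop_excluded and "excluded" in vectors.columns:
        vectors = vectors[~vectors["excluded"].astype(bool)]
    labels = [lab for lab in vectors["label"].unique() if lab != control]
    if control not in set(vectors["label"]):
        raise StatsError(f"control group {control!r} not in the table")
    m = m if m is not None else len(labels)

    grouped = vectors.groupby("label")
    means = grouped[MEASURES].mean()
    variances = grouped[MEASURES].var(ddof=1)
    counts = grouped[MEASURES].count()

    rows = []
    for label in sorted(labels):
        rec: dict = {"label": label}
        _, _, p_vec = _welch_from_moments(
            means.loc[label], variances.loc[label], counts.loc[label],
            means.loc[control], variances.loc[control], counts.loc[control])
        deltas = means.loc[label] - means.loc[control]
        for i, meas in enumerate(MEASURES):
            rec[f"delta_{meas}"] = deltas[meas]
            rec[f"p_{meas}"] = p_vec[i]
            rec[f"n_{meas}"] = int(counts.loc[label, meas])
        rows.append(rec)
    profiles = pd.DataFrame(rows)
    return screen(profiles, m=m, alphas=alphas)


def screen(profiles: pd.DataFrame, m: int,
           alphas: tuple[float, ...] = DEFAULT_ALPHAS) -> pd.DataFrame:
    """Annotate a profile table with Bonferroni tier calls.

    Adds ``tier_<measure>`` per behavior and ``significant`` per drug (true
    when any behavior passes the widest alpha/m threshold).
    """
    tiers = SignificanceTiers(m=m, alphas=alphas)
    out = profiles.copy()
    sig_any = np.zeros(len(out), dtype=bool)
    for meas in MEASURES:
        p = out[f"p_{meas}"].to_numpy(dtype=float)
        out[f"tier_{meas}"] = [tiers.classify(v) for v in p]
        with np.errstate(invalid="ignore"):
            sig_any |= np.nan_to_num(p, nan=1.0) < tiers.thresholds[0]
    out["significant"] = sig_any
    out.attrs["m"] = m
    return out


def profiles_to_records(profiles: pd.DataFrame) -> list[BehavioralProfile]:
    """Dataclass view of a profile table."""
    return [BehavioralProfile(
        label=row["label"],
        delta_pp={m: row[f"delta_{m}"] for m in MEASURES},
        p_values={m: row[f"p_{m}"] for m in MEASURES},
        n={m: row[f"n_{m}"] for m in MEASURES})
        for _, row in profiles.iterrows()]


# ---------------------------------------------------------------------------
# color-coded export
# ---------------------------------------------------------------------------

def delta_to_rgb(delta, style: str = "screen", clip_pp: float = 25.0) -> np.ndarray:
    """Diverging color for a delta in pp, clipped at +-``clip_pp``.

    Decreases shade toward green, increases toward red; zero is white in the
    ``"screen"`` style and black in the ``"cluster"`` style (the tree-viewer
    convention). Undefined deltas map to light gray. Returns float RGB in
    [0, 1], vectorized over ``delta``.
    """
    delta = np.asarray(delta, dtype=float)
    frac = np.clip(delta / clip_pp, -1.0, 1.0)
    rgb = np.empty(delta.shape + (3,))
    neg = frac < 0
    a = np.abs(frac)[..., None]
    if style == "screen":
        # white -> pure green / pure red
        green = np.array([0.0, 1.0, 0.0])
        red = np.array([1.0, 0.0, 0.0])
        white = np.ones(3)
        rgb = np.where(neg[..., None], (1 - a) * white + a * green,
                       (1 - a) * white + a * red)
    elif style == "cluster":
        rgb = np.where(neg[..., None], a * np.array([0.0, 1.0, 0.0]),
                       a * np.array([1.0, 0.0, 0.0]))
    else:
        raise StatsError(f"unknown style {style!r}")
    rgb = np.where(np.isnan(delta)[..., None], 0.85, rgb)
    return rgb


def export_profile_table(profiles: pd.DataFrame, path=None, style: str = "screen",
                         clip_pp: float = 25.0):
    """Color-coded profile table (PNG via matplotlib, or HTML).

    Cell color encodes the delta on the +-``clip_pp`` pp gradient; the tier
    annotation ('*', '**', '***') is printed in each cell. Returns the RGB
    color array that was rendered.
    """
    deltas = profiles[[f"delta_{m}" for m in MEASURES]].to_numpy(dtype=float)
    colors = delta_to_rgb(deltas, style=style, clip_pp=clip_pp)
    if path is None:
        return colors
    path = str(path)
    if path.endswith(".html"):
        _write_html(profiles, colors, path)
        return colors

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows, n_cols = deltas.shape
    fig, ax = plt.subplots(figsize=(0.9 * n_cols + 2.2, 0.32 * n_rows + 1.2))
    ax.imshow(colors, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(n_cols), [DISPLAY_NAMES[m] for m in MEASURES])
    ax.set_yticks(range(n_rows), profiles["label"])
    has_tiers = f"tier_{MEASURES[0]}" in profiles.columns
    for i in range(n_rows):
        for j, meas in enumerate(MEASURES):
            text = f"{deltas[i, j]:+.0f}" if np.isfinite(deltas[i, j]) else ""
            if has_tiers:
                tier = profiles.iloc[i][f"tier_{meas}"]
                if tier != "ns":
                    text += tier
            ax.text(j, i, text, ha="center", va="center", fontsize=7,
                    color="black" if style == "screen" else "white")
    ax.set_title(f"Behavioral profiles (pp vs control, clipped at ±{clip_pp:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return colors


def _write_html(profiles: pd.DataFrame, colors: np.ndarray, path: str) -> None:
    parts = ["<table border='0' cellspacing='0'>",
             "<tr><th>label</th>"
             + "".join(f"<th>{DISPLAY_NAMES[m]}</th>" for m in MEASURES) + "</tr>"]
    for i, (_, row) in enumerate(profiles.iterrows()):
        cells = [f"<td>{row['label']}</td>"]
        for j, meas in enumerate(MEASURES):
            r, g, b = (int(255 * v) for v in colors[i, j])
            val = row[f"delta_{meas}"]
            tier = row.get(f"tier_{meas}", "")
            tier = tier if isinstance(tier, str) and tier != "ns" else ""
            text = f"{val:+.1f}{tier}" if np.isfinite(val) else ""
            cells.append(f"<td style='background-color: rgb({r},{g},{b})'>{text}</td>")
        parts.append("<tr>" + "".join(cells) + "</tr>")
    parts.append("</table>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
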