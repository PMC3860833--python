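"""Incubation cycles, rhythm classification, and actograms.

An incubation cycle is one female bout plus the male bout that follows
it.  Nests whose cycle stays near 24 h keep fixed changeover clock times
(day-night rhythm); cycles away from 24 h make the changeovers drift
across the clock (running rhythm); alternation between the regimes is a
mixed rhythm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._clock import SECONDS_PER_DAY as DAY
from .config import (PATTERN_DAY_NIGHT, PATTERN_MIXED, PATTERN_RUNNING)
from .filters import retained

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
MIN_CYCLES = 4


@dataclass
class CycleSeries:
    """Female+male cycle lengths and changeover clock times of one nest."""

    nest_id: str
    cycles: pd.DataFrame     # start, length_h, male_share, changeover_clock_h
    sufficient: bool         # at least two complete cycles

    def __len__(self):
        return len(self.cycles)


@dataclass
class PatternLabel:
    nest_id: str
    label: str
    median_cycle_h: float
    mean_abs_drift_h_per_day: float
    drift_sign_consistency: float


def cycle_series(bouts: pd.DataFrame, nest_id: str | None = None) -> CycleSeries:
    """Build cycles from each female bout and the male bout that follows.

    ``bouts`` may be a whole-bout table (then ``nest_id`` selects a nest)
    or a single nest's rows.  Bouts must be time-ordered within the nest.
    """
    kept = retained(bouts)
    if nest_id is not None:
        kept = kept[kept["nest_id"] == nest_id]
    elif not kept.empty:
        ids = kept["nest_id"].unique()
        if len(ids) > 1:
            raise ValueError("pass nest_id when the table spans several nests")
        nest_id = ids[0]
    kept = kept.sort_values("start")
    rows = []
    sexes = kept["sex"].to_numpy()
    for i in range(len(kept) - 1):
        if sexes[i] == "F" and sexes[i + 1] == "M":
            f, m = kept.iloc[i], kept.iloc[i + 1]
            if abs(f["end"] - m["start"]) > 1:     # not consecutive
                continue
            cycle_h = (f["length_min"] + m["length_min"]) / 60.0
            rows.append({
                "start": f["start"],
                "length_h": cycle_h,
                "male_share": m["length_min"] / (60.0 * cycle_h),
                "changeover_clock_h": (f["start"] % DAY) / 3600.0,
            })
    cycles = pd.DataFrame(rows, columns=["start", "length_h", "male_share",
                                         "changeover_clock_h"])
    return CycleSeries(nest_id or "", cycles, sufficient=len(cycles) >= 2)


def _changeover_drift(cycles: pd.DataFrame) -> np.ndarray:
    """Per-cycle drift of the female-bout start clock time, h/day.

    Clock differences are unwrapped to the nearest equivalent in
    (-12, 12] h, accumulated into a continuous trajectory, and
    differentiated with central differences, which suppresses day-to-day
    changeover jitter relative to raw consecutive differences.
    """
    clock = cycles["changeover_clock_h"].to_numpy()
    t = cycles["start"].to_numpy() / DAY
    if clock.size < 2:
        return np.empty(0), np.empty(0)
    steps = (np.diff(clock) + 12.0) % 24.0 - 12.0
    traj = clock[0] + np.concatenate(([0.0], np.cumsum(steps)))
    n = traj.size
    drift, span = [], []
    for k in range(1, n - 1):
        dt = t[k + 1] - t[k - 1]
        if dt > 0.5:
            drift.append((traj[k + 1] - traj[k - 1]) / dt)
            span.append(dt)
    if not drift:  # fall back to simple differences on very short records
        d_t = np.diff(t)
        ok = d_t > 0.25
        return steps[ok] / d_t[ok], d_t[ok]
    return np.asarray(drift), np.asarray(span)


def classify_pattern(series: CycleSeries, day_night_tol_h: float = 1.0,
                     drift_tol_h_per_day: float = 0.5,
                     sign_consistency: float = 0.7) -> PatternLabel:
    """Label a nest day-night / running / mixed from its cycle series.

    Day-night: median cycle within ``day_night_tol_h`` of 24 h and mean
    absolute changeover drift at most ``drift_tol_h_per_day``.  Running:
    drift beyond tolerance with a consistent sign over at least
    ``sign_consistency`` of the record.  Everything else is mixed.
    Fractions of the record are time weighted (running cycles are shorter
    than day-night cycles, so cycle counts alone would be biased).
    """
    n = len(series.cycles)
    if n < MIN_CYCLES:
        return PatternLabel(series.nest_id, UNCLASSIFIED,
                            float(series.cycles["length_h"].median())
                            if n else np.nan, np.nan, np.nan)
    med_cycle = float(series.cycles["length_h"].median())
    drift, span = _changeover_drift(series.cycles)
    w = span / span.sum() if drift.size else span
    mean_abs = float(np.sum(w * np.abs(drift))) if drift.size else 0.0
    # fraction of the record drifting beyond tolerance with one sign
    if drift.size:
        w_pos = float(np.sum(w[drift > drift_tol_h_per_day]))
        w_neg = float(np.sum(w[drift < -drift_tol_h_per_day]))
        frac_running = max(w_pos, w_neg)
        consistency = (frac_running / (w_pos + w_neg)
                       if (w_pos + w_neg) > 0 else 1.0)
    else:
        frac_running, consistency = 0.0, 1.0
    if (abs(med_cycle - 24.0) <= day_night_tol_h
            and mean_abs <= drift_tol_h_per_day):
        label = PATTERN_DAY_NIGHT
    elif frac_running >= sign_consistency:
        label = PATTERN_RUNNING
    else:
        label = PATTERN_MIXED
    return PatternLabel(series.nest_id, label, med_cycle, mean_abs,
                        float(consistency))


def classify_study(bouts: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Classify every nest of a bout table; returns one row per nest."""
    rows = []
    for nest_id in retained(bouts)["nest_id"].unique():
        lab = classify_pattern(cycle_series(bouts, nest_id), **kwargs)
        rows.append({
            "nest_id": nest_id, "label": lab.label,
            "median_cycle_h": lab.median_cycle_h,
            "mean_abs_drift": lab.mean_abs_drift_h_per_day,
            "sign_consistency": lab.drift_sign_consistency,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# actograms
# ---------------------------------------------------------------------------

FEMALE_COLOR = "#e8b109"   # yellow
MALE_COLOR = "#1f3b73"     # dark blue
COLD_SHADE = "#d8e6f0"


def render_actogram(bouts: pd.DataFrame, cold_window: tuple[float, float],
                    path, nest_id: str | None = None, title: str | None = None):
    """Raster plot of attendance: one row per day, clock time on x,
    sex-coloured allocation bars, cold window shaded.

    Deterministic for fixed input (fixed figure geometry, no timestamps in
    the payload beyond what the image writer embeds by default).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    kept = retained(bouts)
    if nest_id is not None:
        kept = kept[kept["nest_id"] == nest_id]
    if kept.empty:
        raise ValueError("no bouts to draw")
    kept = kept.sort_values("start")
    day0 = int(kept["start"].min() // DAY)
    day1 = int((kept["end"].max() - 1) // DAY)
    n_days = day1 - day0 + 1

    fig, ax = plt.subplots(figsize=(8, max(2, 0.28 * n_days)))
    w0, w1 = cold_window
    w0h, w1h = w0 / 3600.0, w1 / 3600.0
    for d in range(n_days):
        y = n_days - 1 - d
        if w0h <= w1h:
            ax.axhspan(y, y + 1, xmin=w0h / 24, xmax=w1h / 24,
                       color=COLD_SHADE, lw=0)
        else:  # wraps midnight
            ax.axhspan(y, y + 1, xmin=w0h / 24, xmax=1.0, color=COLD_SHADE, lw=0)
            ax.axhspan(y, y + 1, xmin=0.0, xmax=w1h / 24, color=COLD_SHADE, lw=0)
    for _, row in kept.iterrows():
        color = FEMALE_COLOR if row["sex"] == "F" else MALE_COLOR
        t0, t1 = row["start"], row["end"]
        while t0 < t1:
            d = int(t0 // DAY)
            seg_end = min(t1, (d + 1) * DAY)
            y = n_days - 1 - (d - day0)
            ax.broken_barh([((t0 % DAY) / 3600.0, (seg_end - t0) / 3600.0)],
                           (y + 0.12, 0.76), facecolors=color, lw=0)
            t0 = seg_end
    ax.set_xlim(0, 24)
    ax.set_ylim(0, n_days)
    ax.set_xticks(range(0, 25, 6))
    ax.set_xlabel("time of day (h)")
    ax.set_yticks([n_days - 1 - i + 0.5 for i in range(0, n_days, 5)])
    ax.set_yticklabels([str(day0 + i) for i in range(0, n_days, 5)])
    ax.set_ylabel("day of season")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
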