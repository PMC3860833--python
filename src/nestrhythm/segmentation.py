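"""Incubation-state extraction and RFID fusion.

The nest temperature trace is classified instant-by-instant into
incubated / off states: sitting tight holds the probe at a plateau well
above tundra temperature, a departure shows as a steep decrease, a return
as a steep increase.  The classified states are overlaid with the RFID
reads to allocate each bout to a parent, yielding bout lengths, incubation
constancies, per-bout median z-scored temperatures, and exchange gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._clock import SECONDS_PER_DAY as DAY
from .config import SegmentationParams
from .io import (ABSENT, FEMALE_CODE, MALE_CODE, AlignmentError, GPSTrack,
                 RFIDLog, TemperatureSeries)

log = logging.getLogger(__name__)

DISTURBANCE_RADIUS_M = 210.0   # closest-observer distance regarded as disturbing
DETECTABLE_GAP_S = 5.0         # one RFID tick


class IdentityError(ValueError):
    """RFID contains tags not registered for the nest."""


@dataclass(frozen=True)
class IncubationInterval:
    start: int
    end: int
    incubated: bool

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("interval must have positive length")


# ---------------------------------------------------------------------------
# temperature classification
# ---------------------------------------------------------------------------

def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def classify_incubation(nest_temp: TemperatureSeries,
                        tundra: TemperatureSeries,
                        params: SegmentationParams | None = None
                        ) -> list[IncubationInterval]:
    """Classify each instant of the nest record as incubated or off.

    State machine on the nest-probe grid: an off transition fires on a
    steep temperature decrease (or on the excess over smoothed tundra
    falling below threshold minus hysteresis); an incubated transition
    fires on a steep increase or on sustained excess above threshold.
    Off runs shorter than ``min_off_s`` are merged back.  Transition times
    are placed at the midpoint of the sample step on which they fire, so
    recovered changepoints are within half a native sample of truth on
    noise-free traces.
    """
    if params is None:
        params = SegmentationParams()
    t = nest_temp.times
    if t.size < 2:
        raise AlignmentError("nest record too short to classify")
    if tundra.t_start > t[0] or tundra.t_end < t[-1]:
        raise AlignmentError("tundra series does not cover the nest record")
    dt = nest_temp.nominal_interval
    base = np.interp(t, tundra.times[np.isfinite(tundra.temps)],
                     tundra.temps[np.isfinite(tundra.temps)])
    win = max(1, int(round(params.smoothing_window_min * 60.0 / dt)))
    base = _rolling_median(base, win)
    temp = pd.Series(nest_temp.temps).ffill().bfill().to_numpy()
    excess = temp - base
    slope = np.zeros_like(temp)
    slope[1:] = (temp[1:] - temp[:-1]) * (120.0 / dt)  # deg C per 2 min

    thr = params.min_excess_c
    low = thr - params.hysteresis_c
    inc = excess[0] > thr
    states = np.empty(t.size, dtype=bool)
    states[0] = inc
    for i in range(1, t.size):
        if inc:
            if slope[i] <= params.offset_slope or excess[i] < low:
                inc = False
        else:
            # steep warming, or sustained non-falling excess (re-entry must
            # not fire during the slow cooling tail of a long absence)
            if slope[i] >= params.onset_slope or (
                    excess[i] > thr and excess[i - 1] > thr
                    and slope[i] >= 0.0):
                inc = True
        states[i] = inc

    # run-length encode; transition at the midpoint of the firing step
    edges = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate(([t[0]],
                             (t[edges] - dt // 2) if edges.size else [],
                             [t[-1] + dt]))
    run_states = states[np.concatenate(([0], edges))]
    intervals = [IncubationInterval(int(a), int(b), bool(s))
                 for a, b, s in zip(bounds[:-1], bounds[1:], run_states)]
    intervals = _merge_short_off(intervals, params.min_off_s)
    return intervals


def _merge_short_off(intervals, min_off_s):
    out = []
    for iv in intervals:
        if (not iv.incubated and out and out[-1].incubated
                and iv.end - iv.start < min_off_s):
            # short off run: fold into the surrounding incubated state
            out[-1] = IncubationInterval(out[-1].start, iv.end, True)
            continue
        if out and out[-1].incubated == iv.incubated:
            out[-1] = IncubationInterval(out[-1].start, iv.end, iv.incubated)
        else:
            out.append(iv)
    return out


def incubated_edges(intervals) -> np.ndarray:
    """Edge array of incubated intervals for parity searches."""
    arr = [(iv.start, iv.end) for iv in intervals if iv.incubated]
    return np.asarray(arr, dtype=np.int64).reshape(-1)


def incubated_time_between(edges: np.ndarray, a: float, b: float) -> float:
    """Total incubated seconds inside [a, b) given incubated edge array."""
    if edges.size == 0 or b <= a:
        return 0.0
    starts, ends = edges[0::2], edges[1::2]
    lo = np.clip(starts, a, b)
    hi = np.clip(ends, a, b)
    return float(np.maximum(0, hi - lo).sum())


# ---------------------------------------------------------------------------
# RFID fusion
# ---------------------------------------------------------------------------

def _read_runs(rfid: RFIDLog, majority_window_s: float):
    """Maximal runs of same-tag reads, after absorbing sub-window blips of
    the opposite tag (single-tick misreads)."""
    times = rfid.times
    present = rfid.codes != ABSENT
    rt = times[present]
    rc = rfid.codes[present]
    if rt.size == 0:
        return []
    edge = np.flatnonzero(rc[1:] != rc[:-1]) + 1
    starts = np.concatenate(([0], edge))
    stops = np.concatenate((edge, [rc.size]))
    runs = [(int(rc[a]), int(rt[a]), int(rt[b - 1]), b - a)
            for a, b in zip(starts, stops)]
    # majority vote: drop short runs flanked by a single other tag
    changed = True
    while changed and len(runs) > 2:
        changed = False
        out = [runs[0]]
        i = 1
        while i < len(runs):
            code, first, last, n = runs[i]
            span = last - first + rfid.interval
            if (i + 1 < len(runs) and span < majority_window_s
                    and out[-1][0] == runs[i + 1][0] != code):
                nxt = runs[i + 1]
                out[-1] = (out[-1][0], out[-1][1], nxt[2], out[-1][3] + nxt[3])
                i += 2
                changed = True
            else:
                if out[-1][0] == code:
                    out[-1] = (code, out[-1][1], last, out[-1][3] + n)
                else:
                    out.append(runs[i])
                i += 1
        runs = out
    return runs


def assign_bouts(intervals: list[IncubationInterval], rfid: RFIDLog,
                 metadata: pd.Series,
                 nest_temp: TemperatureSeries | None = None,
                 majority_window_s: float = 120.0):
    """Fuse classified incubation with RFID identity into parental bouts.

    A bout's allocation runs from the parent's first read after the
    previous changeover to the partner's first read; the exchange gap at a
    changeover therefore falls inside the departing parent's allocation and
    lowers its constancy.  Returns ``(bouts, gaps)`` data frames.

    ``metadata`` is the nest's row of the metadata table (needs
    ``tag_female``, ``tag_male``, ``incubation_start_t``).
    """
    tag_sex = {FEMALE_CODE: "F", MALE_CODE: "M"}
    registered = {rfid.tag_of_code.get(FEMALE_CODE), rfid.tag_of_code.get(MALE_CODE)}
    meta_tags = {metadata["tag_female"], metadata["tag_male"]}
    if not registered <= meta_tags:
        raise IdentityError(
            f"RFID tags {sorted(registered - meta_tags)} not in nest metadata")
    sex_of_code = {FEMALE_CODE: "F", MALE_CODE: "M"}
    tick = rfid.interval
    runs = _read_runs(rfid, majority_window_s)
    nest_id = rfid.nest_id
    inc_edges = incubated_edges(intervals)
    t_inc0 = float(metadata["incubation_start_t"])

    if nest_temp is not None:
        z = (nest_temp.temps - np.nanmean(nest_temp.temps)) / np.nanstd(nest_temp.temps)
    bout_rows, gap_rows = [], []
    if len(runs) < 2:
        warnings.warn(f"{nest_id}: fewer than two attendance runs; "
                      "no changeover found", stacklevel=2)
    for k, run in enumerate(runs):
        code, first, last, n_reads = run
        start = first
        if k + 1 < len(runs):
            nxt = runs[k + 1]
            end = nxt[1]
            gap_s = max(0.0, float(nxt[1] - last - tick))
        else:
            end = last + tick
            gap_s = 0.0
        length_s = float(end - start)
        duty_end = end - gap_s
        inc_s = incubated_time_between(inc_edges, start, duty_end)
        constancy = min(1.0, inc_s / length_s) if length_s > 0 else np.nan
        if nest_temp is not None:
            sel = (nest_temp.times >= start) & (nest_temp.times < duty_end)
            sel &= np.searchsorted(inc_edges, nest_temp.times, "right") % 2 == 1 \
                if inc_edges.size else False
            mzt = float(np.nanmedian(z[sel])) if sel.any() else np.nan
        else:
            mzt = np.nan
        mid = 0.5 * (start + end)
        bout_rows.append({
            "nest_id": nest_id,
            "sex": sex_of_code[code],
            "tag": rfid.tag_of_code[code],
            "start": float(start),
            "end": float(end),
            "length_min": length_s / 60.0,
            "constancy": constancy,
            "median_z_temp": mzt,
            "day_of_incubation": (mid - t_inc0) / DAY,
            "gap_s": gap_s,
            "disturbance": 0,
            "n_reads": n_reads,
        })
        if k + 1 < len(runs):
            gap_rows.append({
                "nest_id": nest_id,
                "departure": float(last + tick),
                "return": float(runs[k + 1][1]),
                "duration_s": gap_s,
                "detectable": gap_s >= DETECTABLE_GAP_S,
                "incoming_sex": sex_of_code[runs[k + 1][0]],
                "outgoing_sex": sex_of_code[code],
                "day_of_incubation": (last + tick - t_inc0) / DAY,
            })
    bouts = pd.DataFrame(bout_rows)
    if not bouts.empty:
        bouts["previous_bout_length"] = bouts["length_min"].shift(1)
        bouts["bout_order"] = np.arange(len(bouts))
    gaps = pd.DataFrame(gap_rows)
    return bouts, gaps


# ---------------------------------------------------------------------------
# disturbance
# ---------------------------------------------------------------------------

def flag_disturbance(bouts: pd.DataFrame, tracks: list[GPSTrack],
                     nest_xy: tuple[float, float],
                     radius_m: float = DISTURBANCE_RADIUS_M,
                     step_s: float = 60.0) -> pd.DataFrame:
    """Flag bouts during which a field worker came within ``radius_m`` of
    the nest.  Tracks are linearly interpolated at ``step_s`` resolution."""
    bouts = bouts.copy()
    bouts["disturbance"] = 0
    if not tracks or bouts.empty:
        return bouts
    close_times = []
    nx, ny = nest_xy
    for tr in tracks:
        if len(tr) < 2:
            continue
        grid = np.arange(tr.times[0], tr.times[-1] + 1, step_s)
        xi = np.interp(grid, tr.times, tr.x)
        yi = np.interp(grid, tr.times, tr.y)
        near = np.hypot(xi - nx, yi - ny) <= radius_m
        # only fixes within a walk (gap in fixes > 10 min => off duty)
        idx = np.searchsorted(tr.times, grid)
        idx = np.clip(idx, 1, len(tr) - 1)
        in_walk = (tr.times[idx] - tr.times[idx - 1]) <= 600
        close_times.append(grid[near & in_walk])
    if close_times:
        close = np.sort(np.concatenate(close_times))
        if close.size:
            lo = np.searchsorted(close, bouts["start"].to_numpy())
            hi = np.searchsorted(close, bouts["end"].to_numpy())
            bouts["disturbance"] = (hi > lo).astype(int)
    return bouts


# ---------------------------------------------------------------------------
# study-level convenience
# ---------------------------------------------------------------------------

def extract_study(bundle, params: SegmentationParams | None = None,
                  with_disturbance: bool = True):
    """Run classification + RFID fusion (+ disturbance flags) on every nest
    of a study bundle; returns (bouts, gaps) tables across nests."""
    all_bouts, all_gaps = [], []
    meta = bundle.metadata.set_index("nest_id", drop=False)
    for nest_id in bundle.nest_ids:
        if nest_id not in bundle.rfid:
            continue
        temp = bundle.nest_temp[nest_id]
        ivs = classify_incubation(temp, bundle.tundra[nest_id], params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bouts, gaps = assign_bouts(ivs, bundle.rfid[nest_id],
                                       meta.loc[nest_id], nest_temp=temp)
        if with_disturbance and not bouts.empty:
            bouts = flag_disturbance(
                bouts, bundle.tracks,
                (meta.loc[nest_id, "x_m"], meta.loc[nest_id, "y_m"]))
        all_bouts.append(bouts)
        all_gaps.append(gaps)
    bouts = pd.concat([b for b in all_bouts if not b.empty],
                      ignore_index=True) if all_bouts else pd.DataFrame()
    gaps = pd.concat([g for g in all_gaps if not g.empty],
                     ignore_index=True) if all_gaps else pd.DataFrame()
    return bouts, gaps
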