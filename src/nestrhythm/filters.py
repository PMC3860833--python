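"""Exclusion rules and per-nest descriptive statistics.

Bouts recorded immediately after the parents were first trapped, the bout
during which a nest failed, and bouts ending shortly before hatching are
behaviourally atypical and are excluded before any statistics; nests left
with fewer than four bouts are dropped entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._clock import SECONDS_PER_DAY as DAY
from .io import TemperatureSeries

PRE_HATCH_EXCLUSION_S = 6 * 3600
MIN_BOUTS_PER_NEST = 4

#: exclusion reasons, in the order the rules are applied
REASONS = ("post_capture", "fate_bout", "pre_hatch", "nest_too_few")


class MetadataError(ValueError):
    """Required life-history fields missing from the metadata table."""


class InsufficientDataError(ValueError):
    pass


def apply_exclusions(bouts: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Annotate each bout with its exclusion reason (or none).

    Rules, in order: the first two bouts after the first parent capture;
    the bout during which the nest was deserted or depredated; bouts ending
    within 6 h before the start of hatching; then whole nests retaining
    fewer than four bouts.  The operation is idempotent: reasons are
    recomputed from scratch on every call.

    Returns the table with an ``exclusion`` column; retained bouts have
    ``exclusion`` NA.  "First parent capture" is the earlier of the two
    parents' first capture times.
    """
    if bouts.empty:
        out = bouts.copy()
        out["exclusion"] = pd.Series(dtype="object")
        return out
    meta = metadata.set_index("nest_id")
    needed = {"capture_female_t", "capture_male_t", "fate", "fate_t",
              "hatch_start_t"}
    if not needed <= set(meta.columns):
        raise MetadataError(f"metadata lacks {sorted(needed - set(meta.columns))}")
    bad = meta["fate"].isin(["depredated", "deserted"]) & meta["fate_t"].isna()
    if bad.any():
        raise MetadataError(
            f"nests {list(meta.index[bad])} have a terminal fate but no fate time")

    out = bouts.sort_values(["nest_id", "start"]).reset_index(drop=True).copy()
    out["exclusion"] = pd.array([pd.NA] * len(out), dtype="object")
    for nest_id, grp in out.groupby("nest_id"):
        row = meta.loc[nest_id]
        idx = grp.index
        first_capture = np.nanmin([row["capture_female_t"], row["capture_male_t"]])
        post = idx[grp["start"].to_numpy() >= first_capture][:2]
        out.loc[post, "exclusion"] = "post_capture"
        if row["fate"] in ("deserted", "depredated"):
            holds = (grp["start"] <= row["fate_t"]) & (row["fate_t"] < grp["end"])
            fate_idx = idx[holds.to_numpy()]
            if fate_idx.empty and (grp["end"] <= row["fate_t"]).all():
                fate_idx = idx[-1:]  # fate right at/after the record end
            mask = out.loc[fate_idx, "exclusion"].isna()
            out.loc[fate_idx[mask], "exclusion"] = "fate_bout"
        hatch = row["hatch_start_t"]
        if pd.notna(hatch):
            ends = grp["end"].to_numpy()
            pre = idx[(ends >= hatch - PRE_HATCH_EXCLUSION_S) & (ends <= hatch)]
            mask = out.loc[pre, "exclusion"].isna()
            out.loc[pre[mask], "exclusion"] = "pre_hatch"
    retained = out["exclusion"].isna()
    counts = out.loc[retained, "nest_id"].value_counts()
    small = counts[counts < MIN_BOUTS_PER_NEST].index
    drop = retained & out["nest_id"].isin(small)
    out.loc[drop, "exclusion"] = "nest_too_few"
    return out


def retained(table: pd.DataFrame) -> pd.DataFrame:
    """Bouts that survived the exclusion rules."""
    if "exclusion" not in table.columns:
        return table
    return table[table["exclusion"].isna()]


def nest_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-nest medians and the female share of allocated incubation time.

    Nests where only one sex was recorded are flagged (``share`` NaN).
    """
    kept = retained(table)
    if kept.empty:
        raise InsufficientDataError("no retained bouts to summarise")
    rows = []
    for nest_id, grp in kept.groupby("nest_id"):
        by_sex = grp.groupby("sex")["length_min"]
        total = grp["length_min"].sum()
        f_time = grp.loc[grp["sex"] == "F", "length_min"].sum()
        both = set(grp["sex"]) == {"F", "M"}
        rows.append({
            "nest_id": nest_id,
            "n_bouts": len(grp),
            "median_bout_female": by_sex.median().get("F", np.nan),
            "median_bout_male": by_sex.median().get("M", np.nan),
            "median_bout": grp["length_min"].median(),
            "female_share": f_time / total if both else np.nan,
            "single_sex": not both,
        })
    return pd.DataFrame(rows)


def grouped_median(values, bin_width: float = 5.0) -> float:
    """Median of tick-quantised durations, interpolated within the bin.

    RFID-derived gap durations are multiples of the reader tick; the raw
    sample median of such data flips between adjacent ticks when an atom
    sits near the 50% point.  Tick values arise by (phase-randomised)
    symmetric rounding, so each atom v stands for underlying durations
    near v; the grouped-data median interpolates the empirical CDF
    linearly across the bin centred on the atom containing the half
    point, estimating the median of the underlying continuous durations.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return np.nan
    bins = np.round(v / bin_width) * bin_width
    lo = bins[min(v.size // 2, v.size - 1)]
    n_below = np.searchsorted(bins, lo, side="left")
    n_in = np.searchsorted(bins, lo, side="right") - n_below
    if n_in == 0:
        return float(lo)
    frac = (0.5 * v.size - n_below) / n_in
    return float(lo - bin_width / 2 + bin_width * np.clip(frac, 0.0, 1.0))


# ---------------------------------------------------------------------------
# cold window
# ---------------------------------------------------------------------------

def derive_cold_window(tundra, bin_min: float = 30.0) -> tuple[float, float]:
    """The contiguous daily clock interval during which the mean-by-clock
    tundra temperature lies below the season-wide median.

    ``tundra`` is one series or a list of series pooled together.  Returns
    (start, end) clock seconds; the interval may wrap midnight.
    """
    series = tundra if isinstance(tundra, (list, tuple)) else [tundra]
    times = np.concatenate([s.times for s in series])
    temps = np.concatenate([s.temps for s in series])
    ok = np.isfinite(temps)
    times, temps = times[ok], temps[ok]
    if times.size == 0 or (times.max() - times.min()) < 3 * DAY:
        raise InsufficientDataError("need at least 3 days of tundra record")
    season_median = np.median(temps)
    nbins = int(round(DAY / (bin_min * 60.0)))
    bins = (times % DAY) // (DAY // nbins)
    clock_mean = pd.Series(temps).groupby(bins).mean()
    below = clock_mean.reindex(range(nbins)).to_numpy() < season_median
    if below.all() or not below.any():
        raise InsufficientDataError("tundra record has no diel structure")
    # longest circular run of below-median bins
    ext = np.concatenate([below, below])
    best_len, best_start, cur = 0, 0, 0
    for i, b in enumerate(ext):
        cur = cur + 1 if b else 0
        if cur > best_len and i < nbins + cur:
            best_len, best_start = cur, i - cur + 1
    best_len = min(best_len, nbins)
    start = (best_start % nbins) * (DAY // nbins)
    end = (start + best_len * (DAY // nbins)) % DAY
    return float(start), float(end)


def _overlap_with_window(start, end, w0, w1_abs):
    """Overlap of [start, end) with the absolute window [w0, w1_abs)."""
    return max(0.0, min(end, w1_abs) - max(start, w0))


def cold_period_share(table: pd.DataFrame, tundra,
                      window: tuple[float, float] | None = None,
                      min_coverage: float = 0.9) -> tuple[pd.DataFrame, tuple]:
    """Per nest-day female share of allocated time inside the cold window.

    One window instance opens each day at the window's start clock time.
    Days where less than ``min_coverage`` of the window is covered by
    allocated bouts are dropped (partial records at the edges).
    """
    if window is None:
        window = derive_cold_window(tundra)
    w0, w1 = window
    width = (w1 - w0) % DAY or DAY
    kept = retained(table)
    rows = []
    for nest_id, grp in kept.groupby("nest_id"):
        starts = grp["start"].to_numpy(float)
        ends = grp["end"].to_numpy(float)
        sexes = grp["sex"].to_numpy()
        d0 = int((starts.min() - w0) // DAY)
        d1 = int((ends.max() - w0) // DAY) + 1
        for d in range(d0, d1 + 1):
            a = d * DAY + w0
            b = a + width
            female = total = 0.0
            for s, e, sx in zip(starts, ends, sexes):
                ov = _overlap_with_window(s, e, a, b)
                total += ov
                if sx == "F":
                    female += ov
            if total >= min_coverage * width:
                rows.append({"nest_id": nest_id, "day_index": d,
                             "female_share": female / total,
                             "coverage": total / width})
    return pd.DataFrame(rows), window
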