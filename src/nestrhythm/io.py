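"""Logger-stream containers and file round trips.

Four stream types feed the pipeline: nest/tundra temperature series, RFID
presence logs, field-worker GPS tracks, and a per-nest metadata table.
Files use a small self-describing CSV dialect: a comment header

    # kind=<probe kind> interval=<seconds> id=<probe id> anchor=<date>

followed by a regular CSV body with ISO-8601 timestamps.  GPS tracks are
also accepted as GPX, projected to planar metres about the site centroid.
"""

from __future__ import annotations

import datetime as dt
import io as _io
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._clock import iso_to_seconds, parse_anchor, seconds_to_iso

log = logging.getLogger(__name__)

TEMP_RANGE_C = (-60.0, 60.0)
PROBE_KINDS = ("nest_between_eggs", "fake_egg", "tundra")

ABSENT = 0
FEMALE_CODE = 1
MALE_CODE = 2


class FormatError(ValueError):
    """Unparseable or invalid logger file."""


class EmptyInputError(FormatError):
    """A logger file with no usable samples."""


class AlignmentError(ValueError):
    """Two streams do not share a common time window."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TemperatureSeries:
    """Timestamped temperature samples from one probe."""

    probe_id: str
    probe_kind: str
    times: np.ndarray        # s since season anchor, strictly increasing
    temps: np.ndarray        # deg C; NaN marks a gap on a regular grid
    nominal_interval: int    # s
    anchor: dt.datetime = field(default_factory=lambda: parse_anchor("2011-06-01"))
    n_dropped: int = 0       # out-of-physical-range samples removed on read

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.probe_kind not in PROBE_KINDS:
            raise FormatError(f"unknown probe kind {self.probe_kind!r}")
        if self.times.size != self.temps.size:
            raise FormatError("times and temps differ in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    def __len__(self):
        return self.times.size

    @property
    def t_start(self) -> int:
        return int(self.times[0])

    @property
    def t_end(self) -> int:
        """End of coverage, half-open."""
        return int(self.times[-1]) + self.nominal_interval


@dataclass
class RFIDLog:
    """Per-tick presence of tagged parents at the nest antenna."""

    nest_id: str
    t_start: int             # s, time of the first tick
    interval: int            # s between ticks
    codes: np.ndarray        # int8: 0 absent, 1 female tag, 2 male tag
    tag_of_code: dict        # {1: female tag id, 2: male tag id}
    anchor: dt.datetime = field(default_factory=lambda: parse_anchor("2011-06-01"))

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)

    def __len__(self):
        return self.codes.size

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.interval * np.arange(self.codes.size, dtype=np.int64)

    @property
    def t_end(self) -> int:
        return int(self.t_start + self.interval * self.codes.size)


@dataclass
class GPSTrack:
    """A field worker's movement track in planar site coordinates."""

    person_id: str
    times: np.ndarray        # s, increasing
    x: np.ndarray            # m
    y: np.ndarray            # m
    anchor: dt.datetime = field(default_factory=lambda: parse_anchor("2011-06-01"))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise FormatError("GPS timestamps must be non-decreasing")

    def __len__(self):
        return self.times.size


#: Columns of the nest metadata table, one row per nest.
METADATA_COLUMNS = [
    "nest_id", "x_m", "y_m", "incubation_start_day", "season_start_offset",
    "incubation_start_t", "fate", "fate_t", "hatch_start_t",
    "tag_female", "tag_male", "mass_female", "mass_male",
    "culmen_female", "culmen_male", "radio_female", "radio_male",
    "capture_female_t", "capture_male_t", "probe_type",
]

NEST_FATES = ("hatched", "depredated", "deserted", "unknown")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the nest metadata table against its schema."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata table lacks columns: {missing}")
    bad = set(meta["fate"]) - set(NEST_FATES)
    if bad:
        raise FormatError(f"unknown nest fates: {sorted(bad)}")
    need_time = meta["fate"].isin(["depredated", "deserted"])
    if meta.loc[need_time, "fate_t"].isna().any():
        raise FormatError("depredated/deserted nests need a fate time")
    return meta


# ---------------------------------------------------------------------------
# temperature CSV dialect
# ---------------------------------------------------------------------------

def _header_line(kind: str, interval: int, probe_id: str, anchor: dt.datetime) -> str:
    return (f"# kind={kind} interval={interval} id={probe_id} "
            f"anchor={anchor.date().isoformat()}\n")


def _parse_header(line: str) -> dict:
    if not line.startswith("#"):
        raise FormatError("missing '# kind=... interval=...' header line")
    fields = {}
    for token in line[1:].split():
        if "=" not in token:
            raise FormatError(f"malformed header token {token!r}")
        key, val = token.split("=", 1)
        fields[key] = val
    for required in ("kind", "interval", "id"):
        if required not in fields:
            raise FormatError(f"header lacks {required!r}")
    return fields


def write_temperature(series: TemperatureSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line(series.probe_kind, series.nominal_interval,
                              series.probe_id, series.anchor))
        fh.write("timestamp,temp_c\n")
        stamps = seconds_to_iso(series.times, series.anchor)
        temps = series.temps
        for ts, v in zip(stamps, temps):
            fh.write(f"{ts},{'' if math.isnan(v) else format(v, '.3f')}\n")


def read_temperature(path, probe_kind: str | None = None) -> TemperatureSeries:
    """Read a temperature series, collapsing duplicate timestamps by median
    and dropping physically impossible samples (outside [-60, 60] C)."""
    with open(path) as fh:
        header = _parse_header(fh.readline())
        body = fh.read()
    kind = probe_kind or header["kind"]
    if kind not in PROBE_KINDS:
        raise FormatError(f"unknown probe kind {kind!r}")
    anchor = parse_anchor(header.get("anchor", "2011-06-01"))
    df = pd.read_csv(_io.StringIO(body))
    if not {"timestamp", "temp_c"} <= set(df.columns):
        raise FormatError("temperature body must have timestamp,temp_c columns")
    if df.empty:
        raise EmptyInputError(f"{path}: no samples")
    t = iso_to_seconds(df["timestamp"].to_numpy(), anchor)
    v = df["temp_c"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    # collapse duplicates by median
    if t.size and np.any(np.diff(t) == 0):
        grouped = pd.Series(v).groupby(t).median()
        t = grouped.index.to_numpy(np.int64)
        v = grouped.to_numpy(float)
    finite = ~np.isnan(v)
    in_range = finite & (v >= TEMP_RANGE_C[0]) & (v <= TEMP_RANGE_C[1])
    n_dropped = int(np.count_nonzero(finite & ~in_range))
    keep = in_range | ~finite
    t, v = t[keep], v[keep]
    if n_dropped:
        log.warning("%s: dropped %d out-of-range samples", path, n_dropped)
    if t.size == 0 or not np.isfinite(v).any():
        raise EmptyInputError(f"{path}: no usable samples")
    return TemperatureSeries(header["id"], kind, t, v,
                             int(header["interval"]), anchor,
                             n_dropped=n_dropped)


def align(series: TemperatureSeries, grid_interval: int) -> TemperatureSeries:
    """Nearest-sample assignment onto a regular grid.

    Grid points farther than 1.5x the native interval from any raw sample
    (i.e. inside an outage longer than 3x the native interval) are left
    missing (NaN).
    """
    if grid_interval < series.nominal_interval:
        raise ValueError("grid interval must be >= the native interval")
    if grid_interval == series.nominal_interval and series.times.size > 1 \
            and np.all(np.diff(series.times) == grid_interval):
        return series
    t0 = series.t_start
    grid = np.arange(t0, series.times[-1] + 1, grid_interval, dtype=np.int64)
    idx = np.searchsorted(series.times, grid)
    idx_left = np.clip(idx - 1, 0, series.times.size - 1)
    idx_right = np.clip(idx, 0, series.times.size - 1)
    d_left = np.abs(grid - series.times[idx_left])
    d_right = np.abs(series.times[idx_right] - grid)
    nearest = np.where(d_left <= d_right, idx_left, idx_right)
    dist = np.minimum(d_left, d_right)
    vals = series.temps[nearest].copy()
    vals[dist > 1.5 * series.nominal_interval] = np.nan
    return TemperatureSeries(series.probe_id, series.probe_kind, grid, vals,
                             grid_interval, series.anchor, series.n_dropped)


# ---------------------------------------------------------------------------
# RFID CSV dialect
# ---------------------------------------------------------------------------

def write_rfid(rfid: RFIDLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("rfid", rfid.interval, rfid.nest_id, rfid.anchor))
        fh.write(f"# tag_female={rfid.tag_of_code.get(FEMALE_CODE, '')} "
                 f"tag_male={rfid.tag_of_code.get(MALE_CODE, '')}\n")
        fh.write("timestamp,tag\n")
        stamps = seconds_to_iso(rfid.times, rfid.anchor)
        tags = np.array(["", rfid.tag_of_code.get(FEMALE_CODE, "F"),
                         rfid.tag_of_code.get(MALE_CODE, "M")], dtype=object)
        for ts, code in zip(stamps, rfid.codes):
            fh.write(f"{ts},{tags[code]}\n")


def _parse_comment_tokens(line: str) -> dict:
    fields = {}
    for token in line[1:].split():
        if "=" in token:
            key, val = token.split("=", 1)
            fields[key] = val
    return fields


def read_rfid(path) -> RFIDLog:
    with open(path) as fh:
        header = _parse_header(fh.readline())
        line2 = fh.readline()
        tag_header = _parse_comment_tokens(line2) if line2.startswith("#") else {}
        body = line2 if not line2.startswith("#") else ""
        body += fh.read()
    df = pd.read_csv(_io.StringIO(body), keep_default_na=False)
    if not {"timestamp", "tag"} <= set(df.columns):
        raise FormatError("RFID body must have timestamp,tag columns")
    if df.empty:
        raise EmptyInputError(f"{path}: no records")
    anchor = parse_anchor(header.get("anchor", "2011-06-01"))
    interval = int(header["interval"])
    t = iso_to_seconds(df["timestamp"].to_numpy(), anchor)
    if t.size > 1 and np.any(np.diff(t) != interval):
        raise FormatError("RFID tick spacing is not constant")
    tags = df["tag"].astype(str).to_numpy()
    tag_f = tag_header.get("tag_female") or None
    tag_m = tag_header.get("tag_male") or None
    present = tags != ""
    seen = sorted(set(tags[present]))
    if tag_f is None and tag_m is None:
        if len(seen) > 2:
            raise FormatError(f"more than two tag ids present: {seen}")
        tag_f = seen[0] if seen else "F"
        tag_m = seen[1] if len(seen) > 1 else "M"
    unknown = set(seen) - {tag_f, tag_m}
    if unknown:
        raise FormatError(f"tags not registered for this nest: {sorted(unknown)}")
    codes = np.zeros(t.size, dtype=np.int8)
    codes[tags == tag_f] = FEMALE_CODE
    codes[tags == tag_m] = MALE_CODE
    return RFIDLog(header["id"], int(t[0]), interval, codes,
                   {FEMALE_CODE: tag_f, MALE_CODE: tag_m}, anchor)


# ---------------------------------------------------------------------------
# GPS
# ---------------------------------------------------------------------------

def write_gps(track: GPSTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("gps", 0, track.person_id, track.anchor))
        fh.write("timestamp,x_m,y_m\n")
        stamps = seconds_to_iso(track.times, track.anchor)
        for ts, x, y in zip(stamps, track.x, track.y):
            fh.write(f"{ts},{x:.1f},{y:.1f}\n")


def read_gps(path) -> GPSTrack:
    """Read a GPS track from the CSV dialect or from GPX."""
    with open(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith("<?xml") or "<gpx" in first:
        return _read_gpx(path)
    with open(path) as fh:
        header = _parse_header(fh.readline())
        body = fh.read()
    anchor = parse_anchor(header.get("anchor", "2011-06-01"))
    df = pd.read_csv(_io.StringIO(body))
    if df.empty:
        raise EmptyInputError(f"{path}: no fixes")
    t = iso_to_seconds(df["timestamp"].to_numpy(), anchor)
    return GPSTrack(header["id"], t, df["x_m"].to_numpy(float),
                    df["y_m"].to_numpy(float), anchor)


_EARTH_R = 6_371_000.0


def _read_gpx(path) -> GPSTrack:
    """GPX track points projected equirectangularly about their centroid."""
    tree = ET.parse(path)
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pts = root.iter(f"{ns}trkpt")
    lats, lons, stamps = [], [], []
    for pt in pts:
        lats.append(float(pt.attrib["lat"]))
        lons.append(float(pt.attrib["lon"]))
        el = pt.find(f"{ns}time")
        if el is None or el.text is None:
            raise FormatError(f"{path}: GPX track point without time")
        stamps.append(el.text.rstrip("Z"))
    if not lats:
        raise EmptyInputError(f"{path}: no track points")
    lats = np.asarray(lats)
    lons = np.asarray(lons)
    lat0, lon0 = lats.mean(), lons.mean()
    x = np.radians(lons - lon0) * _EARTH_R * math.cos(math.radians(lat0))
    y = np.radians(lats - lat0) * _EARTH_R
    anchor = parse_anchor("2011-06-01")
    t = iso_to_seconds(np.asarray(stamps, dtype="datetime64[s]"), anchor)
    return GPSTrack(path if isinstance(path, str) else str(path), t, x, y, anchor)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta)
    meta.to_csv(path, index=False, columns=METADATA_COLUMNS)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    return validate_metadata(meta)
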