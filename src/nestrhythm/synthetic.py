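"""Synthetic incubation studies with known ground truth.

Emulates a high-Arctic biparental incubation study: pairs alternate on the
nest in bouts of roughly half a day, changeovers are separated by exchange
gaps with a point mass of effectively instantaneous exchanges, sitting
parents take occasional off-nest breaks, and two logger streams record the
nest — a temperature probe between the eggs (plateau while incubated,
exponential relaxation toward tundra temperature when not) and a 5-s RFID
reader identifying the tagged parent.  Field-worker GPS tracks supply known
disturbance windows.

Two generation modes exist.  ``model`` draws bout lengths from a linear
generative model (sex, day-of-incubation trend, coupling on the previous
bout, nest and residual noise).  ``pattern`` constrains bouts to produce
day-night, running, or mixed incubation rhythms, with female incubation
biased into the cold part of the day.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._clock import SECONDS_PER_DAY as DAY
from ._clock import parse_anchor, parse_clock
from .config import (PATTERN_DAY_NIGHT, PATTERN_MIXED, PATTERN_MODEL,
                     PATTERN_RUNNING, ConfigError, GeneratorConfig)
from .io import (FEMALE_CODE, MALE_CODE, AlignmentError, GPSTrack, RFIDLog,
                 TemperatureSeries, validate_metadata)

_MIN_BOUT_S = 5 * 60  # floor below which generated bouts are truncated


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueSchedule:
    """Ground-truth allocation schedule of one nest.

    Bouts are ordered, non-overlapping, half-open ``[start, end)`` windows
    that strictly alternate sexes.  The exchange gap at the end of a bout
    and the within-bout breaks both belong to that bout's allocation; the
    union of on-nest time, breaks, and the gap tiles the allocation window.
    """

    nest_id: str
    sexes: np.ndarray          # 'F' / 'M' per bout
    starts: np.ndarray         # s
    ends: np.ndarray           # s
    gaps: np.ndarray           # s, exchange gap closing each bout (last = 0)
    breaks: list               # per bout, (k, 2) int array of off intervals
    pattern: str
    t_monitor: tuple           # (t0, t1) monitoring window
    incubation_start_t: float
    plateau: float = 35.0

    def __post_init__(self):
        self.sexes = np.asarray(self.sexes, dtype="U1")
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.gaps = np.asarray(self.gaps, dtype=np.int64)
        n = self.starts.size
        if not (self.ends.size == n == self.sexes.size == self.gaps.size
                == len(self.breaks)):
            raise ValueError("inconsistent schedule arrays")
        if n:
            if np.any(self.ends <= self.starts):
                raise ValueError("bouts must have positive length")
            if np.any(self.starts[1:] != self.ends[:-1]):
                raise ValueError("bouts must tile the record")
            if np.any(self.sexes[1:] == self.sexes[:-1]):
                raise ValueError("bout sexes must alternate")
        for i, br in enumerate(self.breaks):
            br = np.asarray(br, dtype=np.int64).reshape(-1, 2)
            self.breaks[i] = br
            if br.size and (br[:, 0].min() < self.starts[i]
                            or br[:, 1].max() > self.ends[i] - self.gaps[i]):
                raise ValueError("break outside its bout's on-duty window")

    @property
    def n_bouts(self) -> int:
        return self.starts.size

    def bout_frame(self) -> pd.DataFrame:
        """Per-bout ground truth as a table."""
        off = np.array([br[:, 1].sum() - br[:, 0].sum() if br.size else 0
                        for br in self.breaks], dtype=float)
        length = (self.ends - self.starts).astype(float)
        with np.errstate(invalid="ignore"):
            constancy = np.where(length > 0,
                                 (length - off - self.gaps) / length, np.nan)
        mid = (self.starts + self.ends) / 2.0
        return pd.DataFrame({
            "nest_id": self.nest_id,
            "sex": self.sexes,
            "start": self.starts,
            "end": self.ends,
            "length_min": length / 60.0,
            "gap_s": self.gaps.astype(float),
            "off_s": off,
            "constancy": constancy,
            "day_of_incubation": (mid - self.incubation_start_t) / DAY,
        })

    def attendance_intervals(self):
        """(start, end, code) pieces where the allocated parent actually
        sits on the nest (allocation minus breaks minus exchange gap)."""
        pieces = []
        for i in range(self.n_bouts):
            code = FEMALE_CODE if self.sexes[i] == "F" else MALE_CODE
            cursor = self.starts[i]
            duty_end = self.ends[i] - self.gaps[i]
            for b0, b1 in self.breaks[i]:
                if b0 > cursor:
                    pieces.append((cursor, b0, code))
                cursor = b1
            if duty_end > cursor:
                pieces.append((cursor, duty_end, code))
        return pieces

    def on_edges(self) -> np.ndarray:
        """Sorted edge array of on-nest intervals, for parity lookups."""
        pieces = self.attendance_intervals()
        if not pieces:
            return np.empty(0, dtype=np.int64)
        arr = np.array([(a, b) for a, b, _ in pieces], dtype=np.int64)
        return arr.reshape(-1)

    def incubated_at(self, times) -> np.ndarray:
        """True where some parent is sitting on the nest."""
        edges = self.on_edges()
        if edges.size == 0:
            return np.zeros(np.asarray(times).size, dtype=bool)
        return np.searchsorted(edges, np.asarray(times), side="right") % 2 == 1

    def female_share(self) -> float:
        """Female fraction of total allocated time."""
        length = (self.ends - self.starts).astype(float)
        total = length.sum()
        if total == 0:
            return math.nan
        return length[self.sexes == "F"].sum() / total


@dataclass
class NestPlan:
    """Nest-level latent draws shared by the schedule and the metadata."""

    nest_id: str
    start_day: int            # calendar day of incubation start (1 = anchor)
    incubation_start_t: float
    deploy_t: float           # loggers installed / first parent caught
    end_t: float              # monitoring stops (fate or hatch start)
    fate: str
    fate_t: float
    hatch_start_t: float
    pattern: str
    female_frac: float
    drift_h: float
    switch_frac: float        # mixed nests: where the regime changes
    dn_first: bool            # mixed nests: day-night phase first?
    nest_intercept: float     # min, model mode
    plateau: float
    x: float
    y: float
    mass_f: float
    mass_m: float
    culmen_f: float
    culmen_m: float
    radio_f: bool
    radio_m: bool
    capture_f: float
    capture_m: float
    probe_type: int           # 1 = probe between eggs, 0 = fake egg


def _rng(config: GeneratorConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def make_nest_plan(config: GeneratorConfig, nest_index: int) -> NestPlan:
    """Deterministic nest-level draws for nest ``nest_index``."""
    rng = _rng(config, 11, nest_index)
    a, b = config.start_day_beta
    start_day = 1 + int(config.start_day_span * rng.beta(a, b))
    start_day = min(start_day, config.start_day_span)
    t_inc = (start_day - 1) * DAY + rng.uniform(0, DAY)
    lo, hi = config.deploy_day_range
    deploy = t_inc + rng.uniform(lo, hi) * DAY
    hatch = t_inc + config.incubation_days * DAY
    u = rng.random()
    if u < config.frac_hatched:
        fate = "hatched"
    elif u < config.frac_hatched + config.frac_depredated:
        fate = "depredated"
    else:
        fate = "deserted"
    if fate == "hatched":
        fate_t = hatch
        end_t = hatch
    else:
        earliest = min(deploy + 1.0 * DAY, hatch)
        fate_t = rng.uniform(earliest, hatch)
        end_t = fate_t
    pattern = (PATTERN_MODEL if config.mode == "model"
               else [PATTERN_DAY_NIGHT, PATTERN_RUNNING,
                     PATTERN_MIXED][rng.choice(3, p=config.pattern_mix)])
    if pattern == PATTERN_MIXED and (end_t - deploy) < 9 * DAY:
        # too short a record to express a regime change; assign a pure
        # rhythm, preserving the day-night : running ratio of the mix
        p_dn = config.pattern_mix[0] / (config.pattern_mix[0]
                                        + config.pattern_mix[1])
        pattern = PATTERN_DAY_NIGHT if rng.random() < p_dn else PATTERN_RUNNING
    f_mean = config.bout_intercept_female / (config.bout_intercept_female
                                             + config.bout_intercept_male)
    female_frac = float(np.clip(rng.normal(f_mean, config.female_share_sd),
                                0.45, 0.58))
    drift_h = float(rng.choice([-1.0, 1.0]) * rng.uniform(*config.cycle_offsets))
    mass_half = config.mass_sex_diff / 2.0
    capture_f = deploy
    capture_m = deploy + rng.uniform(0.0, 1.0) * DAY
    return NestPlan(
        nest_id=f"N{nest_index:02d}",
        start_day=start_day,
        incubation_start_t=t_inc,
        deploy_t=deploy,
        end_t=end_t,
        fate=fate,
        fate_t=fate_t,
        hatch_start_t=hatch,
        pattern=pattern,
        female_frac=female_frac,
        drift_h=drift_h,
        switch_frac=float(rng.uniform(0.4, 0.6)),
        dn_first=bool(rng.random() < 0.5),
        nest_intercept=float(rng.normal(0.0, math.sqrt(config.nest_intercept_var))),
        plateau=float(rng.normal(config.plateau_temp_mean, config.plateau_temp_sd)),
        x=float(rng.uniform(0, config.site_extent_m)),
        y=float(rng.uniform(0, config.site_extent_m)),
        mass_f=float(rng.normal(config.adult_mass_mean + mass_half, config.mass_sd)),
        mass_m=float(rng.normal(config.adult_mass_mean - mass_half, config.mass_sd)),
        culmen_f=float(rng.normal(config.culmen_female, config.culmen_sd)),
        culmen_m=float(rng.normal(config.culmen_male, config.culmen_sd)),
        radio_f=bool(rng.random() < config.radio_tag_frac),
        radio_m=bool(rng.random() < config.radio_tag_frac),
        capture_f=capture_f,
        capture_m=capture_m,
        probe_type=int(rng.random() < 0.75),
    )


# ---------------------------------------------------------------------------
# bout sequence construction
# ---------------------------------------------------------------------------

def _model_bouts(config, plan, rng, t_stop):
    """Alternating bouts from the generative linear model, minutes -> s."""
    sexes, starts, ends = [], [], []
    t = plan.incubation_start_t
    sex = "F" if rng.random() < 0.5 else "M"
    mean_day = config.incubation_days / 2.0
    prev_centered = 0.0
    sigma = math.sqrt(config.residual_var)
    while t < t_stop:
        day = (t - plan.incubation_start_t) / DAY
        mu = (config.bout_intercept_female
              + (config.sex_effect_male if sex == "M" else 0.0)
              + config.day_effect * (day - mean_day)
              + config.prev_bout_coupling * prev_centered
              + plan.nest_intercept)
        length_min = max(_MIN_BOUT_S / 60.0, rng.normal(mu, sigma))
        sexes.append(sex)
        starts.append(t)
        ends.append(t + length_min * 60.0)
        prev_centered = length_min - config.bout_grand_mean
        t = ends[-1]
        sex = "M" if sex == "F" else "F"
    return sexes, starts, ends


def _day_night_changeovers(config, plan, rng, t_from, t_stop):
    """Clock-anchored female/male changeover times for a day-night nest.

    The female bout start is anchored so that a fraction ``female_night_bias``
    of the cold window falls inside the female bout.
    """
    w0, w1 = config.cold_window_seconds
    window = (w1 - w0) % DAY
    overlap = config.female_night_bias * window
    anchor = (w0 + (window - overlap)) % DAY
    jit = config.changeover_jitter_min * 60.0
    bjit = config.bout_jitter_min * 60.0
    day0 = int(t_from // DAY) - 1
    day1 = int(t_stop // DAY) + 2
    events = []  # (time, sex starting here)
    for k in range(day0, day1):
        fs = k * DAY + anchor + rng.normal(0.0, jit)
        lf = plan.female_frac * DAY + rng.normal(0.0, bjit)
        events.append((fs, "F"))
        events.append((fs + lf, "M"))
    events.sort()
    return events


def _running_changeovers(config, plan, rng, t_from, t_stop, start_clock=None):
    cycle = (24.0 + plan.drift_h) * 3600.0
    bjit = config.bout_jitter_min * 60.0
    if start_clock is None:
        t = t_from - rng.uniform(0, cycle)
    else:
        t = t_from
    events = []
    while t < t_stop + cycle:
        lf = plan.female_frac * cycle + rng.normal(0.0, bjit)
        lm = cycle - lf + rng.normal(0.0, bjit)
        lf = max(lf, _MIN_BOUT_S)
        lm = max(lm, _MIN_BOUT_S)
        events.append((t, "F"))
        events.append((t + lf, "M"))
        t += lf + lm
    return events


def _events_to_bouts(events, t_stop):
    sexes, starts, ends = [], [], []
    for (t0, sex), (t1, _) in zip(events, events[1:]):
        if t1 - t0 < _MIN_BOUT_S:  # jitter collision; skip degenerate slots
            continue
        if sexes and sexes[-1] == sex:
            ends[-1] = t1  # merge same-sex neighbours created by skips
            continue
        sexes.append(sex)
        starts.append(t0)
        ends.append(t1)
    return sexes, starts, ends


def _pattern_bouts(config, plan, rng, t_stop):
    t_from = plan.incubation_start_t
    if plan.pattern == PATTERN_DAY_NIGHT:
        events = _day_night_changeovers(config, plan, rng, t_from, t_stop)
    elif plan.pattern == PATTERN_RUNNING:
        events = _running_changeovers(config, plan, rng, t_from, t_stop)
    else:  # mixed: one regime for part of the record, the other afterwards;
        # the switch lands near the middle of the *monitored* window so both
        # phases are observable after logger deployment
        switch = plan.deploy_t + plan.switch_frac * (t_stop - plan.deploy_t)
        switch = max(switch, t_from + DAY)
        if plan.dn_first:
            head = [e for e in _day_night_changeovers(config, plan, rng,
                                                      t_from, switch)
                    if e[0] < switch]
            tail_start = head[-1][0] if head else switch
            tail = _running_changeovers(config, plan, rng, tail_start, t_stop,
                                        start_clock=0)[1:]
            events = head + tail
        else:
            head = [e for e in _running_changeovers(config, plan, rng,
                                                    t_from, switch)
                    if e[0] < switch]
            tail = [e for e in _day_night_changeovers(config, plan, rng,
                                                      switch, t_stop)
                    if e[0] >= switch]
            events = head + tail
    return _events_to_bouts(events, t_stop)


def _clip_bouts(sexes, starts, ends, t0, t1):
    out_s, out_a, out_b = [], [], []
    for sex, a, b in zip(sexes, starts, ends):
        a2, b2 = max(a, t0), min(b, t1)
        if b2 - a2 >= 60.0:  # ignore sub-minute clipped slivers
            out_s.append(sex)
            out_a.append(a2)
            out_b.append(b2)
    # re-snap shared boundaries after clipping
    for i in range(1, len(out_a)):
        out_a[i] = out_b[i - 1]
    return out_s, out_a, out_b


def _attach_gaps(config, plan, rng, starts, ends):
    """Exchange gap closing each bout; the last bout has none.

    The day trends in gap probability and duration are anchored at the
    midpoint of the monitored record, so ``p_undetectable_gap`` and
    ``gap_median`` are realised marginally over the record as configured.
    """
    if len(starts) == 0:
        return np.zeros(0)
    mean_day = ((starts[0] + ends[-1]) / 2.0 - plan.incubation_start_t) / DAY
    days = (np.asarray(ends[:-1], float) - plan.incubation_start_t) / DAY
    p_all = expit(logit(1.0 - config.p_undetectable_gap)
                  + config.gap_prob_day_logit_slope * (days - mean_day))
    # detectable gaps oversample early days (both day trends are negative),
    # so the duration model is anchored at the detectability-weighted mean
    # day; the realised median detectable gap then matches gap_median
    w_sum = float(np.sum(p_all)) if p_all.size else 0.0
    dur_anchor = (float(np.sum(days * p_all)) / w_sum
                  if w_sum > 0 else mean_day)
    gaps = np.zeros(len(starts))
    for i in range(len(starts) - 1):
        day = days[i]
        p_det = p_all[i]
        if rng.random() < p_det:
            med = config.gap_median * math.exp(
                config.gap_day_log_slope * (day - dur_anchor))
            g = rng.lognormal(math.log(med), config.gap_sigma_log)
            g = float(np.clip(g, 5.0, 0.25 * (ends[i] - starts[i])))
        else:
            g = 0.0
        gaps[i] = g
    return np.round(gaps)


def _attach_breaks(config, plan, rng, sexes, starts, ends, gaps):
    """Within-bout off-nest breaks realising the target constancy."""
    c_f = config.constancy_median_female
    # the sex gap targets the difference in *mean* off-nest fraction; the
    # log-normal draw inflates means over medians by exp(sigma^2 / 2)
    gap_med = (config.constancy_sex_gap / 100.0
               * math.exp(-0.5 * config.constancy_sigma_log ** 2))
    c_m = c_f - gap_med
    min_break = config.break_min_min * 60.0
    margin = 180.0
    all_breaks = []
    for i in range(len(starts)):
        length = ends[i] - starts[i]
        off_med = 1.0 - (c_f if sexes[i] == "F" else c_m)
        off_frac = off_med * math.exp(rng.normal(0.0, config.constancy_sigma_log))
        off_frac = min(off_frac, 0.55)
        span = length - gaps[i] - 2 * margin
        total_off = off_frac * length
        if span <= min_break or total_off < min_break:
            all_breaks.append(np.empty((0, 2), dtype=np.int64))
            continue
        total_off = min(total_off, 0.7 * span)
        k = 1 + rng.poisson(total_off / (config.break_mean_min * 60.0))
        durs = total_off * rng.dirichlet(np.ones(k))
        durs = durs[durs >= min_break]
        if durs.size == 0:
            durs = np.array([total_off])
        free = span - durs.sum()
        if free < 0:
            durs *= 0.9 * span / durs.sum()
            free = span - durs.sum()
        offsets = np.sort(rng.uniform(0.0, free, size=durs.size))
        b_start = starts[i] + margin + offsets + np.concatenate(
            ([0.0], np.cumsum(durs[:-1])))
        br = np.round(np.column_stack([b_start, b_start + durs])).astype(np.int64)
        all_breaks.append(br)
    return all_breaks


def generate_schedule(config: GeneratorConfig, nest_index: int,
                      plan: NestPlan | None = None) -> TrueSchedule:
    """Ground-truth allocation schedule for one nest.

    ``incubation_days == 0`` yields a schedule with zero bouts; an unknown
    mode raises :class:`ConfigError` (via config validation).
    """
    config.validate()
    if plan is None:
        plan = make_nest_plan(config, nest_index)
    rng = _rng(config, 23, nest_index)
    t_stop = plan.end_t
    if config.incubation_days == 0 or t_stop <= plan.deploy_t:
        return TrueSchedule(plan.nest_id, [], [], [], [], [],
                            plan.pattern, (plan.deploy_t, plan.deploy_t),
                            plan.incubation_start_t, plan.plateau)
    if config.mode == "model":
        sexes, starts, ends = _model_bouts(config, plan, rng, t_stop)
    else:
        sexes, starts, ends = _pattern_bouts(config, plan, rng, t_stop)
    sexes, starts, ends = _clip_bouts(sexes, starts, ends, plan.deploy_t, t_stop)
    starts = np.round(np.asarray(starts)).astype(np.int64)
    ends = np.round(np.asarray(ends)).astype(np.int64)
    gaps = _attach_gaps(config, plan, rng, starts, ends).astype(np.int64)
    breaks = _attach_breaks(config, plan, rng, sexes, starts, ends, gaps)
    return TrueSchedule(plan.nest_id, sexes, starts, ends, gaps, breaks,
                        plan.pattern,
                        (float(starts[0]) if starts.size else plan.deploy_t,
                         float(ends[-1]) if ends.size else plan.deploy_t),
                        plan.incubation_start_t, plan.plateau)


# ---------------------------------------------------------------------------
# logger streams
# ---------------------------------------------------------------------------

def synthesize_tundra(config: GeneratorConfig, t0: float = 0.0,
                      t1: float | None = None, probe_id: str = "T00",
                      rng: np.random.Generator | None = None) -> TemperatureSeries:
    """Diel-sinusoid surface tundra temperature with Gaussian noise.

    The sinusoid is parameterised by its warm-half and cold-half daily
    means, so under the defaults the night mean is ~15% of the day mean.
    """
    if config.tundra_temp_interval <= 0:
        raise ConfigError("tundra_temp_interval must be positive")
    if rng is None:
        rng = _rng(config, 31)
    if t1 is None:
        t1 = (config.start_day_span + config.incubation_days + 2) * DAY
    times = np.arange(int(t0), int(t1), config.tundra_temp_interval,
                      dtype=np.int64)
    mean = (config.tundra_day_mean + config.tundra_night_mean) / 2.0
    # half-wave mean of a sinusoid is mean -/+ 2A/pi => A = pi * span / 4
    amp = math.pi * (config.tundra_day_mean - config.tundra_night_mean) / 4.0
    t_min = parse_clock(config.tundra_phase_min)
    temps = mean - amp * np.cos(2 * np.pi * ((times - t_min) % DAY) / DAY)
    if config.tundra_noise_sd > 0:
        temps = temps + rng.normal(0.0, config.tundra_noise_sd, temps.size)
    return TemperatureSeries(probe_id, "tundra", times, temps,
                             config.tundra_temp_interval,
                             parse_anchor(config.season_start))


def synthesize_temperature(schedule: TrueSchedule, tundra: TemperatureSeries,
                           config: GeneratorConfig,
                           rng: np.random.Generator | None = None,
                           probe_kind: str = "nest_between_eggs") -> TemperatureSeries:
    """Nest temperature: plateau while incubated, first-order exponential
    relaxation toward the concurrent tundra temperature otherwise."""
    if rng is None:
        rng = _rng(config, 37, zlib.crc32(schedule.nest_id.encode()))
    t0, t1 = schedule.t_monitor
    if t1 <= t0:
        raise AlignmentError("empty monitoring window")
    if tundra.t_start > t0 or tundra.t_end < t1:
        raise AlignmentError("tundra series does not cover the nest record")
    dt = config.nest_temp_interval
    times = np.arange(int(t0), int(t1), dt, dtype=np.int64)
    base = np.interp(times, tundra.times, tundra.temps)
    on = schedule.incubated_at(times)
    target = np.where(on, schedule.plateau, base)
    tau = config.cooling_time_constant * 60.0
    alpha = math.exp(-dt / tau)
    # relaxation toward the target that held during the elapsed step, so a
    # departure at sample k starts decaying on sample k+1 (the probe still
    # reads the plateau at the instant the bird leaves)
    temps = np.empty(times.size)
    prev = target[0]
    temps[0] = prev
    for i in range(1, times.size):
        goal = target[i - 1]
        prev = goal + (prev - goal) * alpha
        temps[i] = prev
    if config.nest_temp_noise_sd > 0:
        temps = temps + rng.normal(0.0, config.nest_temp_noise_sd, temps.size)
    return TemperatureSeries(schedule.nest_id, probe_kind, times, temps, dt,
                             parse_anchor(config.season_start))


def synthesize_rfid(schedule: TrueSchedule, config: GeneratorConfig,
                    rng: np.random.Generator | None = None,
                    tags: dict | None = None) -> RFIDLog:
    """5-s RFID reads: the allocated parent's tag whenever it is on the nest
    (not in a break or exchange gap) and the read is not dropped."""
    if config.rfid_interval <= 0:
        raise ConfigError("rfid_interval must be positive")
    if rng is None:
        rng = _rng(config, 41, zlib.crc32(schedule.nest_id.encode()))
    t0, t1 = schedule.t_monitor
    tick = config.rfid_interval
    t_start = int(-(-int(t0) // tick) * tick)  # first tick inside the window
    n = max(0, (int(t1) - t_start) // tick)
    codes = np.zeros(n, dtype=np.int8)
    for a, b, code in schedule.attendance_intervals():
        i0 = max(0, -(-(int(a) - t_start) // tick))
        i1 = min(n, -(-(int(b) - t_start) // tick))
        if i1 > i0:
            codes[i0:i1] = code
    if config.rfid_dropout > 0 and n:
        codes[rng.random(n) < config.rfid_dropout] = 0
    if tags is None:
        tags = {FEMALE_CODE: f"{schedule.nest_id}F",
                MALE_CODE: f"{schedule.nest_id}M"}
    return RFIDLog(schedule.nest_id, t_start, tick, codes, tags,
                   parse_anchor(config.season_start))


# ---------------------------------------------------------------------------
# field-worker tracks
# ---------------------------------------------------------------------------

def _make_tracks(config: GeneratorConfig, plans: list) -> list:
    """Daily survey walks between nests; fixes every 30 s at walking speed."""
    rng = _rng(config, 43)
    positions = np.array([(p.x, p.y) for p in plans])
    season_days = config.start_day_span + config.incubation_days + 2
    speed = 1.2      # m/s
    fix_dt = 30.0    # s
    anchor = parse_anchor(config.season_start)
    tracks = []
    for w in range(config.n_field_workers):
        ts, xs, ys = [], [], []
        for day in range(season_days):
            t = day * DAY + rng.uniform(8.0, 16.0) * 3600.0
            k = min(len(plans), int(rng.integers(3, 7)))
            visit = rng.choice(len(plans), size=k, replace=False)
            theta = rng.uniform(0, 2 * np.pi, size=k)
            radius = rng.uniform(20.0, 400.0, size=k)
            pts = positions[visit] + np.column_stack(
                [radius * np.cos(theta), radius * np.sin(theta)])
            here = rng.uniform(0, config.site_extent_m, size=2)
            for target in pts:
                dist = float(np.hypot(*(target - here)))
                steps = max(1, int(dist / (speed * fix_dt)))
                for s in range(1, steps + 1):
                    frac = s / steps
                    ts.append(t + s * fix_dt)
                    xs.append(here[0] + frac * (target[0] - here[0]))
                    ys.append(here[1] + frac * (target[1] - here[1]))
                t += steps * fix_dt
                here = target
        tracks.append(GPSTrack(f"W{w}", np.round(ts).astype(np.int64),
                               np.asarray(xs), np.asarray(ys), anchor))
    return tracks


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """All logger streams, metadata, and ground truth of one synthetic study."""

    config: GeneratorConfig
    plans: list
    schedules: dict            # nest_id -> TrueSchedule
    tundra: dict               # nest_id -> TemperatureSeries
    nest_temp: dict            # nest_id -> TemperatureSeries
    rfid: dict                 # nest_id -> RFIDLog
    tracks: list               # GPSTrack
    metadata: pd.DataFrame

    @property
    def nest_ids(self) -> list:
        return list(self.schedules)

    def true_bouts(self) -> pd.DataFrame:
        frames = [s.bout_frame() for s in self.schedules.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _metadata_row(plan: NestPlan, config: GeneratorConfig) -> dict:
    return {
        "nest_id": plan.nest_id,
        "x_m": plan.x, "y_m": plan.y,
        "incubation_start_day": plan.start_day,
        "season_start_offset": plan.start_day - 1,
        "incubation_start_t": plan.incubation_start_t,
        "fate": plan.fate,
        "fate_t": plan.fate_t,
        "hatch_start_t": plan.hatch_start_t if plan.fate == "hatched" else np.nan,
        "tag_female": f"{plan.nest_id}F", "tag_male": f"{plan.nest_id}M",
        "mass_female": round(plan.mass_f, 1), "mass_male": round(plan.mass_m, 1),
        "culmen_female": round(plan.culmen_f, 1),
        "culmen_male": round(plan.culmen_m, 1),
        "radio_female": int(plan.radio_f), "radio_male": int(plan.radio_m),
        "capture_female_t": plan.capture_f, "capture_male_t": plan.capture_m,
        "probe_type": plan.probe_type,
    }


def generate_study(config: GeneratorConfig) -> StudyBundle:
    """A complete reproducible synthetic study (same seed, same bytes)."""
    config.validate()
    plans = [make_nest_plan(config, i) for i in range(config.n_nests)]
    schedules, tundras, temps, rfids = {}, {}, {}, {}
    for i, plan in enumerate(plans):
        sched = generate_schedule(config, i, plan)
        schedules[plan.nest_id] = sched
        t0, t1 = sched.t_monitor
        pad = DAY
        tundras[plan.nest_id] = synthesize_tundra(
            config, max(0.0, t0 - pad), t1 + pad, probe_id=f"T{i:02d}",
            rng=_rng(config, 31, i))
        if sched.n_bouts:
            temps[plan.nest_id] = synthesize_temperature(
                sched, tundras[plan.nest_id], config, rng=_rng(config, 37, i),
                probe_kind="nest_between_eggs" if plan.probe_type else "fake_egg")
            rfids[plan.nest_id] = synthesize_rfid(
                sched, config, rng=_rng(config, 41, i))
    meta = pd.DataFrame([_metadata_row(p, config) for p in plans])
    validate_metadata(meta)
    tracks = _make_tracks(config, plans)
    return StudyBundle(config, plans, schedules, tundras, temps, rfids,
                       tracks, meta)
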