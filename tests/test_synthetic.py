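"""Ground-truth generator: schedules, logger streams, study bundles."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestrhythm import (GeneratorConfig, generate_schedule, generate_study,
                        synthesize_rfid, synthesize_temperature,
                        synthesize_tundra, write_rfid, write_temperature)
from nestrhythm.config import ConfigError
from nestrhythm._clock import SECONDS_PER_DAY as DAY
from nestrhythm.synthetic import TrueSchedule, make_nest_plan


def noise_free(seed=0, **kw):
    base = dict(seed=seed, mode="model", nest_intercept_var=0.0,
                residual_var=0.0, prev_bout_coupling=0.0, day_effect=0.0,
                p_undetectable_gap=1.0, constancy_median_female=1.0,
                constancy_sex_gap=0.0, nest_temp_noise_sd=0.0,
                tundra_noise_sd=0.0, rfid_dropout=0.0,
                frac_hatched=1.0, frac_depredated=0.0, frac_deserted=0.0)
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerateSchedule:
    def test_zero_incubation_days_gives_empty_schedule(self):
        cfg = GeneratorConfig(seed=0, incubation_days=0)
        sched = generate_schedule(cfg, 0)
        assert sched.n_bouts == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=0, mode="chaotic")

    def test_deterministic_lengths_hit_sex_intercepts(self):
        """With all noise off, female bouts are exactly the female baseline
        and male bouts are baseline plus the male offset."""
        sched = generate_schedule(noise_free(), 0)
        f = sched.bout_frame()
        interior = f.iloc[1:-1]  # first/last bouts are clipped by monitoring
        female = interior[interior["sex"] == "F"]["length_min"]
        male = interior[interior["sex"] == "M"]["length_min"]
        assert len(female) and len(male)
        np.testing.assert_allclose(female, 692.2, atol=1 / 60)
        np.testing.assert_allclose(male, 641.3, atol=1 / 60)

    def test_running_drift_shifts_changeovers_by_fixed_offset(self):
        """-2 h/day running cycle: consecutive same-sex changeovers land
        exactly 2 h earlier each cycle (brute-force diff)."""
        cfg = noise_free(mode="pattern", pattern_mix=(0, 1, 0),
                         cycle_offsets=(2.0, 2.0), bout_jitter_min=0.0,
                         changeover_jitter_min=0.0, female_share_sd=0.0)
        plan = make_nest_plan(cfg, 0)
        assert plan.pattern == "running"
        plan.drift_h = -2.0
        sched = generate_schedule(cfg, 0, plan)
        f = sched.bout_frame()
        female_starts = f[f["sex"] == "F"]["start"].to_numpy()[1:-1]
        diffs = np.diff(female_starts)
        np.testing.assert_allclose(diffs, 22 * 3600, atol=1.5)

    def test_bout_floor(self):
        cfg = noise_free(residual_var=1e6)  # wild draws get truncated
        sched = generate_schedule(cfg, 3)
        if sched.n_bouts:
            interior = sched.bout_frame().iloc[1:-1]
            assert (interior["length_min"] >= 5.0 - 1e-9).all()

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 3))
    def test_allocation_tiling_invariant(self, nest_index, seed):
        """On-nest time + breaks + exchange gap tile each allocation, and
        ground-truth constancy lies in [0, 1]."""
        cfg = GeneratorConfig(seed=seed)
        sched = generate_schedule(cfg, nest_index)
        f = sched.bout_frame()
        if sched.n_bouts == 0:
            return
        on = np.array([b - a for a, b, _ in sched.attendance_intervals()])
        total_on = on.sum()
        alloc = (sched.ends - sched.starts).sum()
        off = f["off_s"].sum() + f["gap_s"].sum()
        assert total_on + off == pytest.approx(alloc)
        assert ((f["constancy"] >= 0) & (f["constancy"] <= 1)).all()
        assert (np.diff(sched.starts) > 0).all()


class TestTundra:
    def test_degenerate_sinusoid_is_constant(self):
        cfg = GeneratorConfig(seed=0, tundra_day_mean=5.0,
                              tundra_night_mean=5.0, tundra_noise_sd=0.0)
        s = synthesize_tundra(cfg, 0, DAY)
        np.testing.assert_allclose(s.temps, 5.0)

    def test_night_day_ratio_near_015(self):
        cfg = GeneratorConfig(seed=0)
        s = synthesize_tundra(cfg, 0, 10 * DAY)
        clock = s.times % DAY
        cold = (clock >= 21.5 * 3600) | (clock < 9.5 * 3600)
        ratio = s.temps[cold].mean() / s.temps[~cold].mean()
        assert ratio == pytest.approx(0.15, abs=0.05)

    def test_minimum_at_configured_phase(self):
        cfg = GeneratorConfig(seed=0, tundra_noise_sd=0.0)
        s = synthesize_tundra(cfg, 0, DAY)
        t_min = s.times[np.argmin(s.temps)] % DAY
        assert abs(t_min - 3.5 * 3600) <= s.nominal_interval


class TestNestTemperature:
    def test_no_bouts_tracks_tundra(self):
        cfg = noise_free(incubation_days=0)
        plan = make_nest_plan(cfg, 0)
        sched = TrueSchedule("N00", [], [], [], [], [], "model",
                             (plan.deploy_t, plan.deploy_t + 2 * DAY),
                             plan.incubation_start_t, plan.plateau)
        tundra = synthesize_tundra(cfg, plan.deploy_t - DAY,
                                   plan.deploy_t + 3 * DAY)
        temp = synthesize_temperature(sched, tundra, cfg)
        base = np.interp(temp.times, tundra.times, tundra.temps)
        assert np.abs(temp.temps - base).mean() < 0.5

    def test_continuous_incubation_sits_at_plateau(self):
        cfg = noise_free()
        t0 = 10 * DAY
        sched = TrueSchedule(
            "N00", ["F", "M"], [t0, t0 + 12 * 3600],
            [t0 + 12 * 3600, t0 + DAY], [0, 0],
            [np.empty((0, 2), int)] * 2, "model", (t0, t0 + DAY), t0,
            plateau=35.0)
        tundra = synthesize_tundra(cfg, t0 - DAY, t0 + 2 * DAY)
        temp = synthesize_temperature(sched, tundra, cfg)
        np.testing.assert_allclose(temp.temps, 35.0, atol=1e-9)

    def test_break_cooling_follows_closed_form(self):
        """A 60-min break with tau = 15 min ends at
        tundra + (plateau - tundra) * exp(-4), the exact relaxation value."""
        cfg = noise_free(tundra_day_mean=8.0, tundra_night_mean=8.0)
        t0 = 10 * DAY
        brk = np.array([[t0 + 6 * 3600, t0 + 6 * 3600 + 3600]])
        sched = TrueSchedule(
            "N00", ["F"], [t0], [t0 + 12 * 3600], [0], [brk], "model",
            (t0, t0 + 12 * 3600), t0, plateau=35.0)
        tundra = synthesize_tundra(cfg, t0 - DAY, t0 + 2 * DAY)
        temp = synthesize_temperature(sched, tundra, cfg)
        i_end = int(np.searchsorted(temp.times, brk[0, 1]))
        assert temp.times[i_end] == brk[0, 1]  # grid-aligned break end
        expected = 8.0 + (35.0 - 8.0) * math.exp(-4.0)
        assert temp.temps[i_end] == pytest.approx(expected, rel=1e-9)


class TestRFIDSynthesis:
    def _schedule(self, gap=0):
        t0 = 10 * DAY
        mid = t0 + 12 * 3600
        return TrueSchedule(
            "N00", ["F", "M"], [t0, mid], [mid, t0 + DAY], [gap, 0],
            [np.empty((0, 2), int)] * 2, "model", (t0, t0 + DAY), t0)

    def test_tick_fraction_matches_ground_truth(self):
        cfg = noise_free()
        sched = self._schedule()
        log = synthesize_rfid(sched, cfg)
        frac = (log.codes == 1).mean()
        on = sum(b - a for a, b, c in sched.attendance_intervals() if c == 1)
        assert abs(frac - on / (DAY)) < 5 / DAY

    def test_total_dropout_gives_empty_log(self):
        cfg = noise_free(rfid_dropout=1.0)
        log = synthesize_rfid(self._schedule(), cfg)
        assert (log.codes == 0).all()

    def test_30s_gap_gives_six_absent_ticks(self):
        cfg = noise_free()
        log = synthesize_rfid(self._schedule(gap=30), cfg)
        codes = log.codes
        switch = np.flatnonzero(codes == 2)[0]
        absent_before = codes[:switch][::-1]
        n_absent = np.argmax(absent_before != 0)
        assert n_absent == 6


class TestGenerateStudy:
    def test_same_seed_same_bytes(self):
        cfg = GeneratorConfig(seed=9, n_nests=3)
        outs = []
        for _ in range(2):
            bundle = generate_study(cfg)
            buf = io.StringIO()
            bundle.metadata.to_csv(buf)
            chunks = [buf.getvalue()]
            for nid in bundle.nest_ids:
                if nid in bundle.nest_temp:
                    chunks.append(np.array2string(bundle.nest_temp[nid].temps))
                    chunks.append(np.array2string(bundle.rfid[nid].codes))
            outs.append("".join(chunks))
        assert outs[0] == outs[1]

    def test_rejects_nonpositive_nests(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=0, n_nests=0)

    def test_adult_mass_distribution(self, default_study):
        meta = default_study.metadata
        masses = np.concatenate([meta["mass_female"], meta["mass_male"]])
        assert masses.mean() == pytest.approx(26.8, abs=0.5)
        assert (meta["mass_female"].mean()
                > meta["mass_male"].mean())

    def test_incubation_start_spread(self, default_study):
        days = default_study.metadata["incubation_start_day"]
        assert 5 <= days.median() <= 9
        assert days.min() >= 1 and days.max() <= 26

    def test_retained_bout_count_at_study_scale(self, default_extraction):
        """Standard filtering of the default 48-nest study keeps a bout
        count in the ballpark of a season of continuous monitoring."""
        bouts, _ = default_extraction
        n = bouts["exclusion"].isna().sum()
        assert 0.8 * 887 <= n <= 1.2 * 887

    def test_ground_truth_constancy_calibration(self, default_study):
        """Median ground-truth female constancy tracks the configured
        target within one percentage point at study scale."""
        tb = default_study.true_bouts()
        med = tb[tb["sex"] == "F"]["constancy"].median()
        assert med == pytest.approx(0.949, abs=0.01)

    def test_female_bouts_converge_to_intercept_at_zero_variance(self):
        cfg = noise_free(seed=4)
        bundle = generate_study(cfg.replace(n_nests=4))
        tb = bundle.true_bouts()
        interior = tb.groupby("nest_id").apply(
            lambda g: g.iloc[1:-1], include_groups=False).reset_index()
        female = interior[interior["sex"] == "F"]["length_min"]
        np.testing.assert_allclose(female, 692.2, atol=1 / 60)
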