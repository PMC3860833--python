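"""Temperature-state classification and RFID fusion."""

import numpy as np
import pandas as pd
import pytest

from nestrhythm import GeneratorConfig, SegmentationParams
from nestrhythm.io import RFIDLog, TemperatureSeries
from nestrhythm.segmentation import (IdentityError, assign_bouts,
                                     classify_incubation, flag_disturbance,
                                     incubated_edges, incubated_time_between)
from nestrhythm.synthetic import (TrueSchedule, generate_schedule,
                                  make_nest_plan, synthesize_rfid,
                                  synthesize_temperature, synthesize_tundra)
from nestrhythm._clock import SECONDS_PER_DAY as DAY


def _flat_tundra(t0, t1, temp=8.0, interval=60):
    t = np.arange(t0, t1, interval)
    return TemperatureSeries("T", "tundra", t, np.full(t.size, temp), interval)


def _meta_row(nest_id="N00", t_inc=0.0):
    return pd.Series({
        "nest_id": nest_id, "tag_female": f"{nest_id}F",
        "tag_male": f"{nest_id}M", "incubation_start_t": t_inc,
        "x_m": 0.0, "y_m": 0.0,
    })


def _rfid_from_codes(codes, t_start=0, nest_id="N00"):
    return RFIDLog(nest_id, t_start, 5, np.asarray(codes, np.int8),
                   {1: f"{nest_id}F", 2: f"{nest_id}M"})


class TestClassifyIncubation:
    def test_nest_equal_to_tundra_is_entirely_off(self):
        t0, t1 = 0, 2 * DAY
        tundra = _flat_tundra(t0 - DAY, t1 + DAY)
        t = np.arange(t0, t1, 120)
        nest = TemperatureSeries("N", "nest_between_eggs", t,
                                 np.full(t.size, 8.0), 120)
        ivs = classify_incubation(nest, tundra)
        assert len(ivs) == 1 and not ivs[0].incubated

    def test_noise_free_break_recovered_within_one_sample(self):
        """Plateau 35 C with one 60-min break: recovered break bounds are
        within one nest-probe sample of the ground truth."""
        cfg = GeneratorConfig(seed=0, nest_temp_noise_sd=0.0,
                              tundra_noise_sd=0.0)
        t0 = 10 * DAY
        b0, b1 = t0 + 6 * 3600, t0 + 7 * 3600
        sched = TrueSchedule("N00", ["F"], [t0], [t0 + 12 * 3600], [0],
                             [np.array([[b0, b1]])], "model",
                             (t0, t0 + 12 * 3600), t0, plateau=35.0)
        tundra = synthesize_tundra(cfg, t0 - DAY, t0 + 2 * DAY)
        nest = synthesize_temperature(sched, tundra, cfg)
        ivs = classify_incubation(nest, tundra)
        offs = [iv for iv in ivs[1:-1] if not iv.incubated]
        assert len(offs) == 1
        assert abs(offs[0].start - b0) <= 120
        assert abs(offs[0].end - b1) <= 120

    def test_state_agreement_on_noisy_study(self, default_study):
        """Per-instant agreement with ground truth across the default
        study is at least 95% of monitored time."""
        agree = total = 0
        for nid, sched in default_study.schedules.items():
            if nid not in default_study.nest_temp:
                continue
            temp = default_study.nest_temp[nid]
            ivs = classify_incubation(temp, default_study.tundra[nid])
            edges = incubated_edges(ivs)
            grid = np.arange(temp.t_start, temp.t_end, 60)
            pred = (np.searchsorted(edges, grid, "right") % 2 == 1
                    if edges.size else np.zeros(grid.size, bool))
            truth = sched.incubated_at(grid)
            agree += int((pred == truth).sum())
            total += grid.size
        assert agree / total >= 0.95

    def test_no_overlap_raises(self):
        tundra = _flat_tundra(0, DAY)
        t = np.arange(5 * DAY, 6 * DAY, 120)
        nest = TemperatureSeries("N", "nest_between_eggs", t,
                                 np.full(t.size, 30.0), 120)
        with pytest.raises(Exception):
            classify_incubation(nest, tundra)


class TestAssignBouts:
    def _ideal_setup(self, gap_ticks=0):
        """12 h female / 12 h male alternation for 4 days, optional gap
        (in 5-s ticks) at every changeover."""
        n_half = 12 * 720  # ticks per 12 h
        codes = []
        for day in range(4):
            for code in (1, 2):
                block = [code] * n_half
                if gap_ticks:
                    block[-gap_ticks:] = [0] * gap_ticks
                codes.extend(block)
        rfid = _rfid_from_codes(codes)
        intervals = [type("IV", (), {})()]
        from nestrhythm.segmentation import IncubationInterval
        intervals = [IncubationInterval(0, 4 * DAY, True)]
        return intervals, rfid

    def test_perfect_alternation(self):
        intervals, rfid = self._ideal_setup()
        bouts, gaps = assign_bouts(intervals, rfid, _meta_row())
        inner = bouts.iloc[1:-1]
        np.testing.assert_allclose(inner["length_min"], 720.0)
        np.testing.assert_allclose(inner["constancy"], 1.0)
        assert (gaps["duration_s"] == 0).all()
        assert list(bouts["sex"])[:4] == ["F", "M", "F", "M"]

    def test_30s_changeover_gap_measured(self):
        intervals, rfid = self._ideal_setup(gap_ticks=6)
        bouts, gaps = assign_bouts(intervals, rfid, _meta_row())
        assert (gaps["duration_s"] == 30.0).all()
        assert gaps["detectable"].all()

    def test_constancy_arithmetic(self):
        """687-min allocation with 34.35 min classified off has constancy
        1 - 34.35/687 = 0.95."""
        from nestrhythm.segmentation import IncubationInterval
        alloc_s = 687 * 60
        off_s = int(34.35 * 60)
        off_start = 3 * 3600
        intervals = [
            IncubationInterval(0, off_start, True),
            IncubationInterval(off_start, off_start + off_s, False),
            IncubationInterval(off_start + off_s, 2 * alloc_s, True),
        ]
        n = alloc_s // 5
        codes = [1] * n + [2] * n
        bouts, _ = assign_bouts(intervals, _rfid_from_codes(codes), _meta_row())
        assert bouts.iloc[0]["constancy"] == pytest.approx(0.95, abs=1e-3)

    def test_unknown_tag_raises_identity_error(self):
        rfid = RFIDLog("N00", 0, 5, np.array([1, 1, 2], np.int8),
                       {1: "STRANGER", 2: "N00M"})
        from nestrhythm.segmentation import IncubationInterval
        with pytest.raises(IdentityError):
            assign_bouts([IncubationInterval(0, 100, True)], rfid, _meta_row())

    def test_single_run_warns(self):
        from nestrhythm.segmentation import IncubationInterval
        rfid = _rfid_from_codes([1] * 1000)
        with pytest.warns(UserWarning):
            assign_bouts([IncubationInterval(0, 5000, True)], rfid,
                         _meta_row())

    def test_allocations_partition_record(self, default_study):
        """Between the first and last changeover, bout allocations tile
        time exactly: no overlaps, no holes."""
        from nestrhythm.segmentation import classify_incubation
        nid = next(iter(default_study.nest_temp))
        temp = default_study.nest_temp[nid]
        ivs = classify_incubation(temp, default_study.tundra[nid])
        meta = default_study.metadata.set_index("nest_id", drop=False)
        bouts, _ = assign_bouts(ivs, default_study.rfid[nid], meta.loc[nid])
        starts = bouts["start"].to_numpy()
        ends = bouts["end"].to_numpy()
        np.testing.assert_array_equal(starts[1:], ends[:-1])

    def test_sex_assignment_accuracy(self, default_study, default_extraction):
        """Assigned bout sex matches ground truth for >= 99% of bouts at
        the default 1% RFID dropout."""
        bouts, _ = default_extraction
        hits = total = 0
        for nid, grp in bouts.groupby("nest_id"):
            truth = default_study.schedules[nid].bout_frame()
            for _, row in grp.iterrows():
                mid = 0.5 * (row["start"] + row["end"])
                j = truth.index[(truth["start"] <= mid) & (mid < truth["end"])]
                if len(j):
                    total += 1
                    hits += int(truth.loc[j[0], "sex"] == row["sex"])
        assert total > 500
        assert hits / total >= 0.99

    def test_within_nest_z_scores_standardised(self, default_study):
        for nid, temp in list(default_study.nest_temp.items())[:5]:
            z = (temp.temps - temp.temps.mean()) / temp.temps.std()
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0)

    def test_constancy_invariant_to_temperature_offset(self):
        """Adding a constant to both probes leaves the classification, and
        hence constancy, unchanged."""
        cfg = GeneratorConfig(seed=3, n_nests=2)
        sched = generate_schedule(cfg, 0)
        plan = make_nest_plan(cfg, 0)
        tundra = synthesize_tundra(cfg, sched.t_monitor[0] - DAY,
                                   sched.t_monitor[1] + DAY)
        from nestrhythm.synthetic import _rng
        nest = synthesize_temperature(sched, tundra, cfg, rng=_rng(cfg, 37, 0))
        ivs1 = classify_incubation(nest, tundra)
        shift = 7.5
        nest2 = TemperatureSeries(nest.probe_id, nest.probe_kind, nest.times,
                                  nest.temps + shift, nest.nominal_interval)
        tundra2 = TemperatureSeries(tundra.probe_id, "tundra", tundra.times,
                                    tundra.temps + shift,
                                    tundra.nominal_interval)
        ivs2 = classify_incubation(nest2, tundra2)
        assert [(iv.start, iv.end, iv.incubated) for iv in ivs1] == \
               [(iv.start, iv.end, iv.incubated) for iv in ivs2]


class TestDisturbance:
    def _bout(self):
        return pd.DataFrame([{"nest_id": "N00", "start": 0.0,
                              "end": 3600.0, "sex": "F"}])

    def _track(self, dist):
        from nestrhythm.io import GPSTrack
        times = np.arange(0, 1200, 30)
        x = np.full(times.size, dist)
        return [GPSTrack("W0", times, x, np.zeros(times.size))]

    def test_worker_at_200m_flags(self):
        out = flag_disturbance(self._bout(), self._track(200.0), (0.0, 0.0))
        assert out["disturbance"].iloc[0] == 1

    def test_worker_at_220m_does_not_flag(self):
        out = flag_disturbance(self._bout(), self._track(220.0), (0.0, 0.0))
        assert out["disturbance"].iloc[0] == 0

    def test_no_tracks_all_zero(self):
        out = flag_disturbance(self._bout(), [], (0.0, 0.0))
        assert (out["disturbance"] == 0).all()


def test_incubated_time_between_partial_overlap():
    edges = np.array([100, 200, 300, 400])
    assert incubated_time_between(edges, 150, 350) == 100.0
    assert incubated_time_between(edges, 0, 1000) == 200.0
    assert incubated_time_between(edges, 210, 290) == 0.0
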