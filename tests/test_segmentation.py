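import numpy as np
import pytest

import canegait as cg
from canegait.exceptions import DataError, ParameterError, SynchronizationError
from canegait.segmentation import (GaitEvent, SegConfig, assemble_strides,
                                   auto_threshold, build_template,
                                   detect_events_msmf, detect_ps_gpd,
                                   events_from_ps_gpd, hysteresis_crossings,
                                   msmf_trace, sync_offset)

FS = 100.0


def _bump(center, width, amp, n, fs=FS):
    t = np.arange(n) / fs
    out = np.zeros(n)
    m = np.abs(t - center) < width / 2
    out[m] = amp * np.sin(np.pi * (t[m] - center + width / 2) / width)
    return out


class TestHysteresisCrossings:
    def test_sine_crossings_interpolated(self):
        t = np.arange(1000) / FS
        x = 10 * np.sin(2 * np.pi * 0.5 * t)
        pos, neg = hysteresis_crossings(x, FS, 1.0)
        np.testing.assert_allclose(pos, [2.0, 4.0, 6.0, 8.0], atol=2e-3)
        np.testing.assert_allclose(neg, [1.0, 3.0, 5.0, 7.0, 9.0], atol=2e-3)

    def test_asymmetric_threshold_rejects_ripple(self):
        t = np.arange(500) / FS
        x = np.full(500, -2.0)
        x += 3.0 * np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)   # small ripple to +1
        x += 30.0 * np.exp(-0.5 * ((t - 3.5) / 0.2) ** 2)   # real bump
        pos_sym, _ = hysteresis_crossings(x, FS, 0.5)
        pos_asym, _ = hysteresis_crossings(x, FS, 0.5, 4.0)
        assert pos_sym.size == 2          # ripple fires a symmetric detector
        assert pos_asym.size == 1         # but not the asymmetric one
        assert 3.0 < pos_asym[0] < 3.5


class TestDetectPS:
    def test_single_bump_at_apex(self):
        g = _bump(3.0, 0.6, 100.0, 800)
        ps = detect_ps_gpd(g, FS, 50.0)
        assert len(ps) == 1
        brute = np.argmax(g) / FS
        assert ps[0].t == pytest.approx(brute, abs=1.5 / FS)

    def test_all_below_threshold(self):
        g = _bump(3.0, 0.6, 40.0, 800)
        assert detect_ps_gpd(g, FS, 50.0) == []

    def test_two_bumps_time_ordered(self):
        g = _bump(2.0, 0.5, 90.0, 800) + _bump(3.0, 0.5, 110.0, 800)
        ps = detect_ps_gpd(g, FS, 50.0)
        assert [round(e.t) for e in ps] == [2, 3]

    def test_close_peaks_keep_larger(self):
        g = _bump(2.0, 0.3, 90.0, 800) + _bump(2.2, 0.3, 110.0, 800)
        ps = detect_ps_gpd(g, FS, 50.0, min_stride_s=0.4)
        assert len(ps) == 1
        assert ps[0].t == pytest.approx(2.2, abs=0.05)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ParameterError):
            detect_ps_gpd(np.zeros(10), FS, 0.0)


def _three_cycle_stream(n=1400):
    """Valleys at IC/TC, peaks at PS, in the style of the shank stream."""
    t = np.arange(n) / FS
    g = np.zeros(n)
    events = []
    ic = 2.0
    for k in range(3):
        tc, ps, ec = ic + 0.7, ic + 0.95, ic + 1.4
        events.append((ic, tc, ps, ec))
        for c, a, w in ((ic, -45, 0.18), (tc, -45, 0.18), (ps, 250, 0.5),
                        (0.5 * (ic + tc), 40, 0.3)):
            m = np.abs(t - c) <= w / 2
            g[m] += a * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / w))
        ic = ec
    m = np.abs(t - ic) <= 0.09
    g[m] += -45 * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - ic) / 0.18))
    return t, g, events


class TestEventsFromPS:
    def test_three_cycles_ec_equals_next_ic(self):
        t, g, events = _three_cycle_stream()
        ps = detect_ps_gpd(g, FS, 100.0)
        ev = events_from_ps_gpd(g, FS, ps)
        ecs = [e.t for e in ev if e.kind == "EC"]
        ics = [e.t for e in ev if e.kind == "IC"]
        # EC of cycle k is exactly the IC of cycle k+1
        assert ecs[0] in ics and ecs[1] in ics
        strides = [s for s in assemble_strides(ev) if s.valid]
        assert len(strides) == 3
        for s, (ic, tc, ps_t, ec) in zip(strides, events):
            assert s.ic.t == pytest.approx(ic, abs=1.0 / FS)
            assert s.tc.t == pytest.approx(tc, abs=1.0 / FS)
            assert s.ps.t == pytest.approx(ps_t, abs=1.0 / FS)
            assert s.ec.t == pytest.approx(ec, abs=1.0 / FS)

    def test_isolated_ps_flat_after_is_invalid(self):
        n = 800
        t = np.arange(n) / FS
        g = np.zeros(n)
        m = np.abs(t - 2.0) <= 0.25
        g[m] = 150 * np.cos(np.pi * (t[m] - 2.0) / 0.5)
        ps = detect_ps_gpd(g, FS, 100.0)
        assert len(ps) == 1
        ev = events_from_ps_gpd(g, FS, ps)
        assert [s for s in assemble_strides(ev) if s.valid] == []

    def test_shank_trial_events_within_one_sample(self, clean_trial,
                                                  clean_trial_result):
        _, shank, truth = clean_trial
        strides = [s for s in clean_trial_result.shank_strides if s.valid]
        tr = truth.shank_events()
        assert len(strides) == len(tr)
        for k, s in enumerate(strides):
            for det, true_t in ((s.ic, tr.ic[k]), (s.tc, tr.tc[k]),
                                (s.ps, tr.ps[k]), (s.ec, tr.ec[k])):
                assert abs(det.t - true_t) <= 1.0 / shank.sample_rate


class TestAutoThreshold:
    def test_homogeneous_scaling(self):
        rng = np.random.default_rng(0)
        g = np.abs(rng.normal(size=1000)) * 50
        assert auto_threshold(2.0 * g) == pytest.approx(
            2.0 * auto_threshold(g), abs=1e-9)

    def test_all_negative_rejected(self):
        with pytest.raises(ParameterError):
            auto_threshold(-np.ones(100))

    def test_separates_shank_lobes_on_control_trial(self, clean_trial):
        from canegait.synth import SHANK_STANCE_FRAC
        _, shank, truth = clean_trial
        thr = auto_threshold(shank.gyro_ap)
        v = truth.strides.shank_v_swing
        assert thr > SHANK_STANCE_FRAC * v.max()   # above every stance lobe
        assert thr < v.min()                        # below every swing peak


class TestTemplateAndTrace:
    def test_template_matches_true_bump(self, clean_trial):
        cane, _, truth = clean_trial
        cane_p, _ = cg.preprocess(cane)
        fs = cane.sample_rate
        tmpl = build_template(cane_p.strain, fs, 5)
        # correlate against one true loading bump
        row = truth.strides.iloc[6]
        seg = cane_p.strain[int(row.ic * fs):int(row.tc * fs)]
        seg_r = np.interp(np.linspace(0, 1, tmpl.size),
                          np.linspace(0, 1, seg.size), seg)
        r = np.corrcoef(tmpl, seg_r)[0, 1]
        assert r > 0.99

    def test_template_duration_near_stance(self, clean_trial):
        cane, _, truth = clean_trial
        cane_p, _ = cg.preprocess(cane)
        fs = cane.sample_rate
        tmpl = build_template(cane_p.strain, fs, 5)
        mean_stance = truth.strides.stance_s.head(5).mean()
        assert tmpl.size / fs == pytest.approx(mean_stance, rel=0.10)

    def test_too_few_bumps(self):
        x = np.full(2000, -2.0)
        x[500:600] = 50.0
        with pytest.raises(DataError):
            build_template(x, FS, 5)

    def test_trace_self_similarity(self):
        tmpl = _bump(1.0, 1.0, 1.0, 200)[50:150]
        x = np.zeros(1000)
        x[400:500] = tmpl
        tr = msmf_trace(x, tmpl / np.linalg.norm(tmpl))
        assert tr.max() == pytest.approx(1.0, abs=1e-9)
        assert abs(np.argmax(tr) - 400) <= 1
        assert np.max(np.abs(tr)) <= 1.0 + 1e-9

    def test_trace_anticorrelation(self):
        tmpl = _bump(1.0, 1.0, 1.0, 200)[50:150]
        x = np.zeros(1000)
        x[400:500] = -tmpl
        tr = msmf_trace(x, tmpl)
        assert tr[400] <= 0.0

    def test_zero_energy_template_rejected(self):
        with pytest.raises(ParameterError):
            msmf_trace(np.ones(100), np.zeros(10))


class TestDetectMSMF:
    def test_noise_free_recall_precision_one(self, clean_trial,
                                             clean_trial_result):
        cane, _, truth = clean_trial
        strides = clean_trial_result.msmf_strides
        tr = truth.strides
        assert len(strides) == len(tr)          # precision = recall = 1
        for k, s in enumerate(strides):
            assert abs(s.ic.t - tr.ic[k]) <= 1.0 / cane.sample_rate

    def test_threshold_above_trace_max_gives_empty(self, clean_trial):
        cane, _, _ = clean_trial
        cane_p, _ = cg.preprocess(cane)
        fs = cane.sample_rate
        tmpl = build_template(cane_p.strain, fs, 5)
        cfg = SegConfig(similarity_threshold=1.0)
        assert detect_events_msmf(cane_p.strain, cane_p.gyro_x, fs, tmpl,
                                  cfg) == []

    def test_flat_strain_gives_empty(self):
        tmpl = _bump(1.0, 1.0, 1.0, 200)[50:150]
        strain = np.full(2000, -2.0)
        gyro = np.zeros(2000)
        assert detect_events_msmf(strain, gyro, FS, tmpl) == []

    def test_scale_invariance(self, clean_trial):
        cane, _, _ = clean_trial
        cane_p, _ = cg.preprocess(cane)
        fs = cane.sample_rate
        tmpl = build_template(cane_p.strain, fs, 5)
        a = detect_events_msmf(cane_p.strain, cane_p.gyro_x, fs, tmpl)
        b = detect_events_msmf(3.7 * cane_p.strain, cane_p.gyro_x, fs, tmpl)
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert ea.t == pytest.approx(eb.t, abs=1e-6)

    def test_event_order_invariant(self, clean_trial_result,
                                   noisy_trial_result):
        for res in (clean_trial_result, noisy_trial_result):
            for s in res.msmf_strides:
                assert s.ic.t < s.tc.t < s.ps.t < s.ec.t


class TestAssembleStrides:
    def _events(self, times_kinds):
        return [GaitEvent(k, t, "GPD") for t, k in times_kinds]

    def test_eight_events_two_strides(self):
        ev = self._events([(0.0, "IC"), (0.5, "TC"), (0.8, "PS"), (1.2, "EC"),
                           (1.2, "IC"), (1.7, "TC"), (2.0, "PS"), (2.4, "EC")])
        strides = assemble_strides(ev)
        assert [s.valid for s in strides] == [True, True]

    def test_missing_final_ec(self):
        ev = self._events([(0.0, "IC"), (0.5, "TC"), (0.8, "PS"), (1.2, "EC"),
                           (1.2, "IC"), (1.7, "TC"), (2.0, "PS")])
        strides = assemble_strides(ev)
        assert strides[0].valid and not strides[1].valid
        assert "EC" in strides[1].reason

    def test_order_violation(self):
        ev = self._events([(0.0, "IC"), (0.8, "PS"), (0.9, "TC"), (1.2, "EC")])
        strides = assemble_strides(ev)
        assert not strides[0].valid
        assert strides[0].reason == "order"


class TestSync:
    def test_offset_recovered(self, clean_trial):
        cane, shank, truth = clean_trial
        cane_p, shank_p = cg.preprocess(cane, shank)
        rec = sync_offset(cane_p, shank_p)
        assert rec == pytest.approx(truth.offset_s, abs=0.010)

    def test_offset_recovered_with_noise(self, noisy_trial):
        cane, shank, truth = noisy_trial
        cane_p, shank_p = cg.preprocess(cane, shank)
        rec = sync_offset(cane_p, shank_p)
        assert rec == pytest.approx(truth.offset_s, abs=0.010)

    def test_flat_shank_rejected(self, clean_trial):
        cane, shank, _ = clean_trial
        flat = cg.ShankRecording(time=shank.time,
                                 gyro_ap=np.zeros(len(shank)),
                                 sample_rate=shank.sample_rate)
        with pytest.raises(SynchronizationError):
            sync_offset(cane, flat)

    def test_crossing_free_cane_rejected(self, clean_trial):
        _, shank, _ = clean_trial
        n = 1000
        t = np.arange(n) / 231.0
        flat = cg.CaneRecording(
            time=t, strain=np.full(n, -2.0), gyro_x=np.zeros(n),
            gyro_y=np.zeros(n), gyro_z=np.zeros(n), accel_x=np.zeros(n),
            accel_y=np.zeros(n), accel_z=np.zeros(n), sample_rate=231.0)
        with pytest.raises(SynchronizationError):
            sync_offset(flat, shank)
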