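import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import canegait as cg
from canegait.exceptions import ParameterError
from canegait.synth import draw_study_parameters


def _control_draw(profile, **overrides):
    d = dict(stance_s=profile.stance_s.mean, swing_s=profile.swing_s.mean,
             v_swing=profile.v_swing.mean, v_stance=profile.v_stance.mean,
             ps_offset_s=profile.ps_offset_s.mean,
             strain_peak=profile.strain_peak.mean,
             strain_peak_offset_s=profile.strain_peak_offset_s.mean,
             stride_length_m=profile.stride_length_m.mean,
             gpd_ic_lag_s=profile.gpd_ic_lag_s.mean)
    d.update(overrides)
    return d


class TestProfiles:
    def test_eleven_conditions(self, profiles):
        assert len(profiles) == 11

    @pytest.mark.parametrize("cond,field,value", [
        ("control", "v_swing", 246.5),
        ("control", "v_stance", 156.4),
        ("control", "strain_peak", 110.6),
        ("control", "stride_length_m", 1.1),
        ("upstairs", "stride_length_m", 0.3),
        ("dorsiflexion", "v_stance", 124.6),
        ("downhill", "v_stance", 189.6),
        ("long_cane", "stride_length_m", 1.3),
    ])
    def test_table_means(self, profiles, cond, field, value):
        assert getattr(profiles[cond], field).mean == value

    def test_ic_lag_is_negated_ic_difference(self, profiles):
        assert profiles["control"].gpd_ic_lag_s.mean == pytest.approx(0.0126)
        assert profiles["upstairs"].gpd_ic_lag_s.mean == pytest.approx(0.0787)

    def test_cane_lengths(self, profiles):
        assert profiles["long_cane"].cane_length_m == pytest.approx(0.9508)
        assert profiles["short_cane"].cane_length_m == pytest.approx(0.8492)

    def test_profile_invariants(self, profiles):
        for p in profiles.values():
            assert p.v_swing.mean > p.v_stance.mean >= 0
            assert 0 < p.ps_offset_s.mean < p.swing_s.mean
            assert 0 < p.strain_peak_offset_s.mean < p.stance_s.mean
            assert p.stride_length_m.mean >= 0


class TestSynthStride:
    def test_strain_apex_time_and_value(self, control_profile):
        draw = _control_draw(control_profile)
        strain, gyro, shank, ev = cg.synth_stride(control_profile, draw)
        fs = 231.0
        i = np.argmax(strain)
        t_apex = i / fs
        assert abs(t_apex - (ev["ic"] + draw["strain_peak_offset_s"])) <= 0.5 / fs
        assert strain.max() == pytest.approx(draw["strain_peak"], abs=0.05)

    def test_swing_integral_matches_pendulum_angle(self, control_profile):
        draw = _control_draw(control_profile)
        strain, gyro, shank, ev = cg.synth_stride(control_profile, draw)
        fs = 231.0
        t = np.arange(gyro.size) / fs
        m = (t > ev["tc"]) & (t <= ev["ec"])
        theta = np.trapezoid(gyro[m], t[m])
        expected = math.degrees(2 * math.asin(1.1 / (2 * 0.9)))
        assert theta == pytest.approx(expected, abs=0.5)

    def test_short_stride_integral(self, profiles):
        prof = profiles["upstairs"]
        draw = _control_draw(prof, ps_offset_s=prof.ps_offset_s.mean)
        strain, gyro, shank, ev = cg.synth_stride(prof, draw)
        fs = 231.0
        t = np.arange(gyro.size) / fs
        m = (t > ev["tc"]) & (t <= ev["ec"])
        theta = np.trapezoid(gyro[m], t[m])
        expected = math.degrees(2 * math.asin(0.3 / 1.8))
        assert theta == pytest.approx(expected, abs=0.5)

    def test_zero_sweep_limit(self, control_profile):
        # a zero-length stride needs a proportionally small swing velocity,
        # and the post-swing valley must fall entirely after EC
        draw = _control_draw(control_profile, stride_length_m=0.0,
                             v_swing=1e-4, v_stance=0.0, gpd_ic_lag_s=0.1)
        strain, gyro, shank, ev = cg.synth_stride(control_profile, draw)
        fs = 231.0
        t = np.arange(gyro.size) / fs
        m = (t > ev["tc"]) & (t <= ev["ec"])
        assert abs(np.trapezoid(np.radians(gyro[m]), t[m])) < 1e-6

    def test_unsatisfiable_draw_raises(self, control_profile):
        draw = _control_draw(control_profile, stride_length_m=1.79,
                             v_swing=40.0, v_stance=20.0)
        with pytest.raises(ParameterError):
            cg.synth_stride(control_profile, draw)


class TestGenerateTrial:
    def test_determinism(self, control_profile):
        cfg = cg.StudyConfig(n_participants=1, strides_per_trial=5, seed=0)
        a = cg.generate_trial(control_profile, cfg, seed=21)
        b = cg.generate_trial(control_profile, cfg, seed=21)
        np.testing.assert_array_equal(a[0].strain, b[0].strain)
        np.testing.assert_array_equal(a[1].gyro_ap, b[1].gyro_ap)
        pd.testing.assert_frame_equal(a[2].strides, b[2].strides)
        assert a[2].offset_s == b[2].offset_s

    def test_truth_event_structure(self, noisy_trial):
        _, _, truth = noisy_trial
        tr = truth.strides
        assert (tr.ic < tr.tc).all() and (tr.tc < tr.ps).all() \
            and (tr.ps < tr.ec).all()
        # EC of stride k is IC of stride k+1
        np.testing.assert_allclose(tr.ec.values[:-1], tr.ic.values[1:])
        assert len(tr) == 10

    def test_quiet_lead_in(self, noisy_trial):
        cane, shank, truth = noisy_trial
        assert truth.strides.ic.iloc[0] >= 2.0
        assert 0.0 < truth.offset_s < truth.strides.ic.iloc[0] - 2.0

    def test_degenerate_profile_reproduces_table_value(self, control_profile):
        zeroed = {f.name: (dataclasses.replace(getattr(control_profile, f.name), sd=0.0)
                           if isinstance(getattr(control_profile, f.name), cg.Gaussian)
                           else getattr(control_profile, f.name))
                  for f in dataclasses.fields(control_profile)}
        prof = cg.ConditionProfile(**zeroed)
        cfg = cg.StudyConfig(n_participants=1, strides_per_trial=4, seed=0,
                             noise_sd_strain=0.0, noise_sd_gyro=0.0)
        cane, _, truth = cg.generate_trial(prof, cfg, seed=5)
        fs = cane.sample_rate
        for _, row in truth.strides.iterrows():
            sl = slice(int(row.ic * fs), int(row.tc * fs))
            assert cane.strain[sl].max() == pytest.approx(110.6, abs=0.05)


class TestGenerateStudy:
    def test_trial_count(self, profiles):
        cfg = cg.StudyConfig(n_participants=2, strides_per_trial=3,
                             conditions=("control", "dorsiflexion"), seed=1)
        trials = cg.generate_study(cfg)
        assert len(trials) == 4
        assert {(t.participant, t.condition) for t in trials} == {
            (0, "control"), (0, "dorsiflexion"),
            (1, "control"), (1, "dorsiflexion")}

    def test_participant_shift_shared_across_conditions(self):
        # with a pure between-participant split the standardized participant
        # offset is identical for both conditions of the same person
        cfg = cg.StudyConfig(n_participants=6, strides_per_trial=12,
                             conditions=("control", "fogged_glasses"), seed=3,
                             between_participant_sd_scale=1.0)
        df = draw_study_parameters(cfg)
        profs = cg.default_profiles()
        z = {}
        for cond in cfg.conditions:
            g = profs[cond].strain_peak
            sub = df[df.condition == cond].groupby("participant")["strain_peak"].mean()
            z[cond] = (sub - g.mean) / g.sd
        np.testing.assert_allclose(z["control"], z["fogged_glasses"], atol=1e-9)

    def test_variance_decomposition(self):
        # between_participant_sd_scale = 0 removes between-participant spread
        base = dict(n_participants=12, strides_per_trial=20,
                    conditions=("control",))
        d0 = draw_study_parameters(cg.StudyConfig(**base, seed=5,
                                                  between_participant_sd_scale=0.0))
        d1 = draw_study_parameters(cg.StudyConfig(**base, seed=5,
                                                  between_participant_sd_scale=1.0))
        v0 = d0.groupby("participant")["strain_peak"].mean().var()
        v1 = d1.groupby("participant")["strain_peak"].mean().var()
        assert v0 < v1 / 5.0

    def test_grand_mean_near_table_value(self):
        cfg = cg.StudyConfig(n_participants=30, strides_per_trial=40,
                             conditions=("control",), seed=9)
        df = draw_study_parameters(cfg)
        sem = 2 * 55.5 / math.sqrt(len(df))
        assert df.v_swing.mean() == pytest.approx(246.5, abs=sem)

    def test_drawn_parameters_respect_invariants(self):
        cfg = cg.StudyConfig(n_participants=4, strides_per_trial=15,
                             conditions=("upstairs", "downhill"), seed=13)
        df = draw_study_parameters(cfg)
        assert (df.v_swing > df.v_stance).all()
        assert (df.stride_length_m >= 0).all()
        assert (df.ps_offset_s < df.swing_s).all()
        assert (df.strain_peak_offset_s < df.stance_s).all()
        assert (df.gpd_ic_lag_s > 0).all()

    def test_study_config_yaml_round_trip(self, tmp_path):
        cfg = cg.StudyConfig(n_participants=3, strides_per_trial=7,
                             conditions=("control",), seed=42)
        path = tmp_path / "study.yaml"
        cfg.to_yaml(path)
        back = cg.StudyConfig.from_yaml(path)
        assert back.n_participants == 3 and back.seed == 42
        assert tuple(back.conditions) == ("control",)


class TestGeneratorSelfConsistency:
    """Raw waveforms reproduce the drawn parameters before any filtering."""

    def test_feature_recovery_on_raw_signals(self, clean_trial):
        cane, shank, truth = clean_trial
        fs = cane.sample_rate
        from canegait.segmentation import GaitEvent, Stride
        for _, row in truth.strides.iterrows():
            stride = Stride(GaitEvent("IC", row.ic, "MSMF"),
                            GaitEvent("TC", row.tc, "MSMF"),
                            GaitEvent("PS", row.ps, "MSMF"),
                            GaitEvent("EC", row.ec, "MSMF"))
            f = cg.stride_features(stride, cane, 0.9)
            assert f.max_pv_swing == pytest.approx(row.v_swing, rel=1e-3)
            assert f.max_pv_stance == pytest.approx(row.v_stance, rel=1e-3)
            assert f.max_strain == pytest.approx(row.strain_peak, rel=1e-3)
            assert f.max_pv_time_wrt_tc == pytest.approx(
                1e3 * row.ps_offset_s, abs=1e3 / fs)
            assert f.max_strain_time_wrt_ic == pytest.approx(
                1e3 * row.strain_peak_offset_s, abs=1e3 / fs)
            assert f.stride_length == pytest.approx(row.stride_length_m,
                                                    rel=0.01)
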