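"""Synthetic study generator: truth dynamics, observation models, determinism."""
import numpy as np
import pytest

from hemoconcord.core import Device, Modality, StudyArm
from hemoconcord.synthetic import (
    DeviceModel,
    InterventionKind,
    InterventionSegment,
    SyntheticConfig,
    generate_study,
    generate_truth,
    observe,
    study_segments,
)


def flat_config(**kw):
    """Baseline-only config with no physiologic wander."""
    kw.setdefault("segments", [InterventionSegment(InterventionKind.BASELINE,
                                                   0, 3600, 0.0)])
    kw.setdefault("duration", 3600.0)
    kw.setdefault("variability_cv", 0.0)
    kw.setdefault("n_animals", 1)
    return SyntheticConfig(**kw)


def seg_mean(series, start, end):
    t = series.times
    return np.nanmean(series.values[(t >= start) & (t < end)])


class TestTruth:
    def test_baseline_only_is_flat(self):
        cfg = flat_config()
        truth = generate_truth(cfg, 0)
        assert np.allclose(truth[Modality.SV].values, cfg.baseline["SV0"])
        assert np.allclose(truth[Modality.HR].values, cfg.baseline["HR0"])
        assert np.allclose(truth[Modality.MAP].values, cfg.baseline["MAP0"])

    def test_co_equals_sv_times_hr_exactly(self):
        cfg = SyntheticConfig(seed=3, n_animals=1)
        truth = generate_truth(cfg, 0)
        np.testing.assert_array_equal(
            truth[Modality.CO].values,
            truth[Modality.SV].values * truth[Modality.HR].values / 1000.0)

    @pytest.mark.parametrize("kind,modality,sign", [
        (InterventionKind.VASODILATOR, Modality.MAP, -1),
        (InterventionKind.VASOPRESSOR, Modality.MAP, +1),
        (InterventionKind.POS_INOTROPE, Modality.CO, +1),
        (InterventionKind.NEG_INOTROPE, Modality.CO, -1),
        (InterventionKind.BLEED, Modality.SV, -1),
        (InterventionKind.PULM_VASOPRESSOR, Modality.PAP, +1),
    ])
    def test_signed_effect_rules(self, kind, modality, sign):
        segs = [InterventionSegment(InterventionKind.BASELINE, 0, 1200, 0.0),
                InterventionSegment(kind, 1200, 2400, 0.5)]
        cfg = flat_config(segments=segs, duration=3000.0)
        truth = generate_truth(cfg, 0)
        base = seg_mean(truth[modality], 600, 1200)
        effect = seg_mean(truth[modality], 1800, 2400)  # past the lag transient
        assert sign * (effect - base) > 0

    def test_bleed_then_resuscitate_restores_stroke_volume(self):
        segs = [InterventionSegment(InterventionKind.BASELINE, 0, 600, 0.0),
                InterventionSegment(InterventionKind.BLEED, 600, 1500, 0.3),
                InterventionSegment(InterventionKind.RESUSCITATE, 1500, 2400, 0.3)]
        cfg = flat_config(segments=segs, duration=2400.0)
        sv = generate_truth(cfg, 0)[Modality.SV]
        pre = seg_mean(sv, 0, 600)
        end_bleed = seg_mean(sv, 1300, 1500)
        end_resus = seg_mean(sv, 2200, 2400)
        assert end_bleed < pre
        assert end_resus > end_bleed

    def test_baseline_map_in_physiologic_band(self, study2_records):
        for rec in study2_records:
            mapp = rec.ground_truth[Modality.MAP]
            assert 65.0 < seg_mean(mapp, 300, 1200) < 85.0

    def test_pulm_vasopressor_rejected_in_study1(self):
        segs = study_segments(StudyArm.STUDY2)
        with pytest.raises(ValueError, match="PULM_VASOPRESSOR"):
            SyntheticConfig(arm=StudyArm.STUDY1, segments=segs)


class TestObserve:
    def test_identity_model_reproduces_truth_at_cadence(self):
        cfg = flat_config(variability_cv=0.03)
        truth = generate_truth(cfg, 0)
        m = DeviceModel(Device.UFS, cadence=5, delay=0, smooth_window=0,
                        scale=1, noise_cv=0, hr_noise_cv=0)
        co = next(s for s in observe(truth, m, 1) if s.modality is Modality.CO)
        idx = (co.times / 5).astype(int)
        np.testing.assert_allclose(co.values, truth[Modality.CO].values[idx],
                                   rtol=1e-12)

    def test_injected_delay_appears_as_cross_correlation_peak(self):
        cfg = SyntheticConfig(seed=5, n_animals=1)
        truth = generate_truth(cfg, 0)
        m = DeviceModel(Device.PAC_CCO, cadence=60, delay=300.0,
                        smooth_window=0, noise_cv=0, hr_noise_cv=0)
        co = next(s for s in observe(truth, m, 1) if s.modality is Modality.CO)
        tv = truth[Modality.CO]
        lags = np.arange(0, 601, 60)
        corrs = []
        for lag in lags:
            src = np.interp(co.times - lag, tv.times, tv.values)
            corrs.append(np.corrcoef(src, co.values)[0, 1])
        assert lags[int(np.argmax(corrs))] == 300

    def test_relative_unit_stream_has_constant_ratio_when_noiseless(self):
        cfg = SyntheticConfig(seed=5, n_animals=1)
        truth = generate_truth(cfg, 0)
        m = DeviceModel(Device.EIT, cadence=5, scale=0.025, noise_cv=0,
                        unit="a.u.", hr_noise_cv=0)
        sv = next(s for s in observe(truth, m, 1) if s.modality is Modality.SV)
        idx = (sv.times / 5).astype(int)
        ratio = sv.values / truth[Modality.SV].values[idx]
        np.testing.assert_allclose(ratio, 0.025, rtol=1e-12)
        assert sv.unit == "a.u."

    def test_excessive_delay_rejected(self):
        cfg = flat_config(duration=600.0,
                          segments=[InterventionSegment(
                              InterventionKind.BASELINE, 0, 600, 0.0)])
        truth = generate_truth(cfg, 0)
        m = DeviceModel(Device.PAC_CCO, cadence=60, delay=550.0,
                        smooth_window=120.0)
        with pytest.raises(ValueError, match="exceeds"):
            observe(truth, m, 1)


class TestStudy:
    def test_same_seed_reproduces_identically(self):
        a = generate_study(SyntheticConfig(seed=7, n_animals=2))
        b = generate_study(SyntheticConfig(seed=7, n_animals=2))
        for ra, rb in zip(a, b):
            assert ra.animal_id == rb.animal_id
            for sa, sb in zip(ra.streams, rb.streams):
                np.testing.assert_array_equal(sa.values, sb.values)
                np.testing.assert_array_equal(sa.times, sb.times)

    def test_study1_has_no_flow_probe_streams(self):
        recs = generate_study(SyntheticConfig(seed=1, n_animals=2,
                                              arm=StudyArm.STUDY1))
        assert all(not any(s.device is Device.UFS for s in r.streams)
                   for r in recs)

    def test_study2_default_has_seven_flow_probe_animals(self, study2_records):
        assert len(study2_records) == 7
        assert all(any(s.device is Device.UFS for s in r.streams)
                   for r in study2_records)

    def test_injected_delays_inside_documented_envelope(self):
        recs = generate_study(SyntheticConfig(seed=11, n_animals=10))
        delays = [r.injected["pac_cco_delay"] for r in recs]
        assert all(282.0 <= d <= 666.0 for d in delays)

    def test_noiseless_devices_reproduce_shifted_truth_exactly(self):
        from dataclasses import replace
        cfg = SyntheticConfig(seed=2, n_animals=1)
        cfg.device_models = {d: replace(m, noise_cv=0.0, hr_noise_cv=0.0,
                                        scale=1.0, smooth_window=0.0,
                                        clock_offset=0.0, delay=0.0)
                             for d, m in cfg.device_models.items()}
        rec = generate_study(cfg)[0]
        truth = rec.ground_truth
        for s in rec.streams:
            if s.modality not in (Modality.CO, Modality.SV, Modality.HR):
                continue
            tv = truth[s.modality]
            idx = np.round(s.times / 5).astype(int)
            np.testing.assert_allclose(s.values, tv.values[idx], rtol=1e-10)
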