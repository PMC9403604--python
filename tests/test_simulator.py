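import numpy as np
import pytest

from aeye import (
    DistractorSpec,
    EyeAppearance,
    FilterParams,
    WaveformSpec,
    filtered_stack,
    gen_trace,
    make_dataset,
    render_clip,
    synth_clip,
)
from aeye.simulator import PX_PER_DEG_AT_240


class TestGenTrace:
    def test_fixation_is_constant_with_no_annotations(self):
        trace = gen_trace(WaveformSpec(kind="none"), rate=60, duration=2, seed=0)
        assert np.allclose(trace.positions, 0.0)
        assert trace.n_beats == 0 and not trace.is_nystagmus

    def test_slow_phase_sample_counts(self):
        spec = WaveformSpec(kind="jerk_linear", slow_phase_duration=250.0, n_beats=4, onset=0.5)
        trace = gen_trace(spec, rate=60, duration=3, seed=0)
        assert trace.n_beats == 4
        for (s0, s1), _fast in trace.beat_annotations:
            assert s1 - s0 == 15  # 0.250 s × 60 Hz

    def test_slow_phase_velocity_recovered_by_regression(self):
        spec = WaveformSpec(
            kind="jerk_linear", slow_phase_duration=300.0, amplitude=2.0,
            n_beats=3, onset=0.4, direction=(1.0, 0.0),
        )
        trace = gen_trace(spec, rate=60, duration=3, seed=0)
        (s0, s1), _ = trace.beat_annotations[0]
        t = np.arange(s0, s1) / 60.0
        slope = np.polyfit(t, trace.positions[s0:s1, 0], 1)[0]
        expected = 2.0 * PX_PER_DEG_AT_240 / ((s1 - s0) / 60.0)
        assert abs(slope - expected) / expected < 0.01

    def test_pendular_spectral_peak(self):
        spec = WaveformSpec(kind="pendular", pendular_frequency=3.0, n_beats=27,
                            amplitude=2.0, onset=0.5)
        trace = gen_trace(spec, rate=60, duration=10, seed=0)
        x = trace.positions[:, 0] - trace.positions[:, 0].mean()
        freqs = np.fft.rfftfreq(len(x), d=1 / 60.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x))[1:]) + 1]
        assert abs(peak - 3.0) < 0.2

    def test_velocity_decreasing_slows_within_phase(self):
        spec = WaveformSpec(kind="jerk_velocity_decreasing", slow_phase_duration=330.0,
                            amplitude=2.0, n_beats=2, decay_constant=10.0)
        trace = gen_trace(spec, rate=60, duration=2, seed=0)
        (s0, s1), _ = trace.beat_annotations[0]
        v = np.diff(trace.positions[s0:s1, 0])
        assert v[0] > v[-1] > 0

    def test_distractors_never_create_beats(self):
        distract = DistractorSpec(
            blink_times=(0.5, 1.2), square_wave_jerks=((0.8, 1.0, 0.25),),
            drift_velocity=0.5, tremor_noise_sd=0.05,
        )
        trace = gen_trace(WaveformSpec(kind="none"), distract, rate=60, duration=2, seed=1)
        assert trace.n_beats == 0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_trace(WaveformSpec(), rate=60, duration=0.01)


class TestRenderClip:
    def test_static_noise_free_clip_is_constant_and_filters_to_zero(self, quiet_appearance):
        trace = gen_trace(WaveformSpec(kind="none"), rate=60, duration=1, seed=0)
        clip = render_clip(trace, quiet_appearance, resolution=(60, 80), seed=0)
        assert np.all(clip.frames == clip.frames[0])
        stack = filtered_stack(clip, FilterParams(beta=0.25))
        assert np.all(stack.images == 0.0)

    def test_darkest_pixel_tracks_the_pupil(self, quiet_appearance):
        spec = WaveformSpec(kind="jerk_linear", amplitude=3.0, n_beats=3, onset=0.2)
        trace = gen_trace(spec, rate=60, duration=1.5, seed=0)
        clip = render_clip(trace, quiet_appearance, resolution=(120, 160), seed=0)
        scale = 120 / 240.0
        pupil_r = quiet_appearance.pupil_radius * scale
        for i in range(0, clip.n_frames, 10):
            y, x = np.unravel_index(np.argmin(clip.frames[i]), clip.frames[i].shape)
            cx = 80 + trace.positions[i, 0] * scale
            cy = 60 + trace.positions[i, 1] * scale
            assert np.hypot(x - cx, y - cy) <= pupil_r + 1.0

    def test_seeded_rendering_is_bitwise_deterministic(self):
        kw = dict(rate=60.0, duration=1.0, resolution=(30, 40), seed=11)
        spec = WaveformSpec(kind="jerk_linear", n_beats=3, onset=0.2)
        a = synth_clip(spec, **kw)
        b = synth_clip(spec, **kw)
        assert np.array_equal(a.frames, b.frames)
        assert a.label == b.label == 1

    def test_label_follows_two_beat_rule(self):
        one_beat = synth_clip(
            WaveformSpec(kind="jerk_linear", n_beats=1, onset=0.2),
            rate=60, duration=1.5, resolution=(30, 40), seed=0,
        )
        two_beats = synth_clip(
            WaveformSpec(kind="jerk_linear", n_beats=2, onset=0.2),
            rate=60, duration=1.5, resolution=(30, 40), seed=0,
        )
        assert one_beat.label == 0 and two_beats.label == 1

    def test_eye_out_of_frame_rejected(self):
        trace = gen_trace(WaveformSpec(kind="none"), rate=60, duration=0.5, seed=0)
        with pytest.raises(ValueError):
            render_clip(trace, EyeAppearance(gaze_offset=(500.0, 0.0)), resolution=(60, 80))

    def test_blink_occludes_the_eye(self, quiet_appearance):
        distract = DistractorSpec(blink_times=(0.5,), blink_duration=200.0)
        trace = gen_trace(WaveformSpec(kind="none"), distract, rate=60, duration=1, seed=0)
        clip = render_clip(trace, quiet_appearance, resolution=(60, 80), seed=0)
        mid = int(0.5 * 60)
        # pupil hidden at blink centre: darkest pixel is much brighter
        assert clip.frames[mid].min() > clip.frames[0].min() + 50


class TestLabelSoundness:
    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_specs_label_iff_two_beats(self, seed):
        rng = np.random.default_rng(seed)
        spec = WaveformSpec(
            kind=str(rng.choice(["jerk_linear", "jerk_velocity_decreasing", "none"])),
            slow_phase_duration=float(rng.uniform(150, 350)),
            amplitude=float(rng.uniform(1, 3)),
            n_beats=int(rng.integers(0, 4)),
            onset=0.3,
        )
        distract = DistractorSpec(
            blink_times=(0.8,), drift_velocity=float(rng.uniform(-0.3, 0.3)),
            tremor_noise_sd=0.03,
        )
        trace = gen_trace(spec, distract, rate=60, duration=2.5, seed=seed)
        clip = render_clip(trace, EyeAppearance(), resolution=(30, 40), seed=seed)
        assert clip.label == int(trace.n_beats >= 2)
        if spec.kind == "none" or spec.n_beats < 2:
            assert clip.label == 0

    def test_separability_sanity_motion_energy(self, quiet_appearance):
        noisy = EyeAppearance(sensor_noise_sd=2.0)
        nyst, fix = [], []
        for seed in range(4):
            spec = WaveformSpec(kind="jerk_linear", amplitude=2.5, n_beats=5, onset=0.2)
            c1 = synth_clip(spec, appearance=noisy, rate=60, duration=2,
                            resolution=(60, 80), seed=seed)
            c0 = synth_clip(WaveformSpec(kind="none"), appearance=noisy, rate=60,
                            duration=2, resolution=(60, 80), seed=seed)
            nyst.append(np.abs(np.diff(c1.frames.astype(float), axis=0)).mean())
            fix.append(np.abs(np.diff(c0.frames.astype(float), axis=0)).mean())
        assert np.mean(nyst) > np.mean(fix)


class TestMakeDataset:
    def test_exact_class_balance(self):
        clips = make_dataset(n_videos=12, class_ratio=0.5, rate=60, duration=2,
                             resolution=(24, 32), patients=3, seed=0)
        labels = [c.label for c in clips]
        assert sum(labels) == 6 and len(clips) == 12

    def test_every_patient_contributes_both_classes(self):
        clips = make_dataset(n_videos=16, class_ratio=0.5, rate=60, duration=2,
                             resolution=(24, 32), patients=4, seed=1)
        by_patient = {}
        for c in clips:
            by_patient.setdefault(c.patient_id, set()).add(c.label)
        assert len(by_patient) == 4
        assert all(v == {0, 1} for v in by_patient.values())

    def test_eccentric_fraction_rounding(self):
        clips = make_dataset(n_videos=435, class_ratio=0.5, rate=60, duration=2,
                             resolution=(24, 32), patients=30,
                             eccentric_fraction=0.443, seed=2)
        n_ecc = sum(c.condition == "eccentric" for c in clips)
        assert n_ecc == 193

    def test_seed_determinism(self):
        kw = dict(n_videos=6, rate=60, duration=2, resolution=(24, 32), patients=2)
        a = make_dataset(seed=5, **kw)
        b = make_dataset(seed=5, **kw)
        assert all(np.array_equal(x.frames, y.frames) for x, y in zip(a, b))
        assert [x.label for x in a] == [y.label for y in b]

    def test_infeasible_constraints_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(n_videos=4, class_ratio=0.5, patients=3, duration=2,
                         resolution=(24, 32))
        with pytest.raises(ValueError):
            make_dataset(n_videos=10, class_ratio=0.99, duration=2, patients=1,
                         resolution=(24, 32))
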