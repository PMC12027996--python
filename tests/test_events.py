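import numpy as np
import pytest

from gazestate.events import (DetectorConfig, GazeEventDetector, SampleStream,
                              compute_velocity, detect_blinks,
                              detect_saccades, event_f1, read_asc_samples,
                              segment_fixations)
from gazestate.geometry import DEFAULT_GEOMETRY, deg_to_px
from gazestate.synth import (GeneratorParams, TrialMeta, generate_trial,
                             _raised_cosine_ramp)


def make_stream(x_deg, y_deg=None, rate=500.0, pupil=None):
    """Build a binocular stream from a degree-space trace (both eyes equal)."""
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.zeros_like(x_deg) if y_deg is None else np.asarray(y_deg)
    n = len(x_deg)
    t = np.arange(n) * 1000.0 / rate
    px = deg_to_px(x_deg, axis="x")
    py = deg_to_px(y_deg, axis="y")
    if pupil is None:
        pupil = np.full(n, 1000.0)
    return SampleStream(t, px.copy(), py.copy(), px.copy(), py.copy(),
                        pupil.copy(), pupil.copy())


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        stream = make_stream(np.zeros(100))
        vel = compute_velocity(stream, "left")
        interior = vel["speed"][5:-5]
        assert np.allclose(interior, 0.0, atol=1e-9)

    def test_linear_ramp_constant_velocity(self):
        # 0.02 deg/sample at 500 Hz -> 10 deg/s, zero acceleration
        stream = make_stream(np.arange(200) * 0.02 - 2.0)
        vel = compute_velocity(stream, "left")
        assert np.allclose(vel["vx"][5:-5], 10.0, rtol=1e-3)
        assert np.allclose(vel["accel"][5:-5], 0.0, atol=2.0)

    def test_short_stream_errors(self):
        stream = make_stream(np.zeros(4))
        with pytest.raises(ValueError):
            compute_velocity(stream, "left")

    def test_peak_velocity_recovery(self, noiseless_params):
        meta = TrialMeta("S01", "gaze_stability", "RR", 1, seed=2)
        stream, truth = generate_trial(meta, noiseless_params)
        vel = compute_velocity(stream, "left")
        for e in truth.saccades:
            i = (stream.time_ms >= e.onset_ms) & \
                (stream.time_ms < e.offset_ms)
            assert np.nanmax(vel["speed"][i]) == \
                pytest.approx(e.peak_velocity, rel=0.05)


class TestBlinks:
    def test_pad_arithmetic(self):
        pupil = np.full(1000, 900.0)
        pupil[400:475] = 0.0            # 150 ms dropout at 500 Hz
        stream = make_stream(np.zeros(1000), pupil=pupil)
        blinks = detect_blinks(stream, "left")
        assert len(blinks) == 1
        assert blinks[0].duration_ms == pytest.approx(250.0)  # +2 x 50 pad

    def test_short_dropout_ignored(self):
        pupil = np.full(500, 900.0)
        pupil[100:105] = 0.0            # 10 ms
        stream = make_stream(np.zeros(500), pupil=pupil)
        cfg = DetectorConfig(min_blink_ms=50.0)
        assert detect_blinks(stream, "left", cfg) == []

    def test_no_dropouts(self):
        stream = make_stream(np.zeros(300))
        assert detect_blinks(stream, "left") == []


def synthetic_saccade_trace(amplitude, rate=500.0, slope=50.0, pad_s=0.5):
    """Fixation, one raised-cosine saccade, fixation."""
    n_pad = int(pad_s * rate)
    vp = slope * amplitude
    n_sacc = int(round(2 * amplitude / vp * rate))
    ramp = _raised_cosine_ramp(n_sacc) * amplitude
    return np.concatenate([np.zeros(n_pad), ramp,
                           np.full(n_pad, amplitude)])


class TestSaccades:
    def test_noiseless_five_degree_saccade(self):
        stream = make_stream(synthetic_saccade_trace(5.0))
        vel = compute_velocity(stream, "left")
        events = detect_saccades(stream, vel, "left")
        assert len(events) == 1
        assert events[0].amplitude_deg == pytest.approx(5.0, rel=0.02)
        assert events[0].peak_velocity >= events[0].avg_velocity > 0

    def test_subthreshold_noise_no_saccades(self):
        rng = np.random.default_rng(0)
        stream = make_stream(rng.normal(0.0, 0.02, 2000))
        vel = compute_velocity(stream, "left")
        assert detect_saccades(stream, vel, "left") == []

    def test_two_saccades_separated_by_blink(self):
        rate = 500.0
        trace = np.concatenate([
            synthetic_saccade_trace(4.0, rate),            # sacc ~0.5 s
            np.full(int(0.8 * rate), 4.0),
            4.0 + synthetic_saccade_trace(3.0, rate)])     # sacc later
        pupil = np.full(len(trace), 800.0)
        blink_start = int(1.6 * rate)
        pupil[blink_start:blink_start + int(0.15 * rate)] = 0.0
        stream = make_stream(trace, pupil=pupil)
        # gaze is also invalid during the blink
        stream.lx[pupil == 0] = np.nan
        stream.rx[pupil == 0] = np.nan
        vel = compute_velocity(stream, "left")
        blinks = detect_blinks(stream, "left")
        saccades = detect_saccades(stream, vel, "left", blinks)
        assert len(blinks) == 1
        assert len(saccades) == 2
        b = blinks[0]
        for s in saccades:
            assert s.offset_ms <= b.onset_ms or s.onset_ms >= b.offset_ms

    def test_missing_velocity_errors(self):
        stream = make_stream(np.zeros(100))
        with pytest.raises(ValueError):
            detect_saccades(stream, {}, "left")

    def test_monotone_in_threshold(self, static_trial):
        stream, _, _ = static_trial
        counts = []
        for thr in (20.0, 30.0, 45.0, 60.0, 100.0, 200.0):
            cfg = DetectorConfig(velocity_threshold=thr,
                                 extend_threshold=min(15.0, thr / 2),
                                 accel_threshold=1e12)
            vel = compute_velocity(stream, "left")
            blinks = detect_blinks(stream, "left", cfg)
            counts.append(len(detect_saccades(stream, vel, "left",
                                              blinks, cfg)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestFixations:
    def test_one_saccade_two_fixations(self):
        stream = make_stream(synthetic_saccade_trace(5.0))
        vel = compute_velocity(stream, "left")
        saccades = detect_saccades(stream, vel, "left")
        fixations = segment_fixations(stream, saccades, [])
        assert len(saccades) == 1
        assert len(fixations) == 2

    def test_all_blink_no_fixations(self):
        pupil = np.zeros(500)
        stream = make_stream(np.zeros(500), pupil=pupil)
        stream.lx[:] = np.nan
        blinks = detect_blinks(stream, "left")
        assert segment_fixations(stream, [], blinks) == []

    def test_fixation_count_is_saccades_plus_one(self, detector):
        params = GeneratorParams(trial_duration=12.0, fixation_noise_sd=0.0,
                                 blink_rate=0.0)
        meta = TrialMeta("S01", "gaze_stability", "RR", 1, seed=4)
        stream, truth = generate_trial(meta, params)
        events = detector.detect(stream)["left"]
        saccades = [e for e in events if e.kind == "saccade"]
        fixations = [e for e in events if e.kind == "fixation"]
        assert len(saccades) == len(truth.saccades)
        assert len(fixations) == len(saccades) + 1

    def test_partition_of_valid_samples(self, detector, static_trial):
        stream, _, _ = static_trial
        events = detector.detect(stream)["left"]
        cover = np.zeros(len(stream), dtype=int)
        for e in events:
            i = (stream.time_ms >= e.onset_ms) & \
                (stream.time_ms < e.offset_ms)
            cover[i] += 1
        # no sample belongs to two events
        assert cover.max() <= 1
        # uncovered valid samples form only short (discarded) runs
        valid = np.isfinite(stream.lx)
        uncovered = valid & (cover == 0)
        step_ms = 1000.0 / stream.sampling_rate
        max_run = 0
        run = 0
        for u in uncovered:
            run = run + 1 if u else 0
            max_run = max(max_run, run)
        cfg = detector.config
        assert max_run * step_ms < max(cfg.min_fixation_ms,
                                       cfg.min_saccade_ms)

    def test_detector_recovery_single_trial(self, detector,
                                            noiseless_params):
        meta = TrialMeta("S01", "smooth_pursuit", "RG", 1, seed=6)
        stream, truth = generate_trial(meta, noiseless_params)
        events = detector.detect(stream)["left"]
        det_sacc = [e for e in events if e.kind == "saccade"]
        det_blink = [e for e in events if e.kind == "blink"]
        assert event_f1(det_sacc, truth.saccades) >= 0.95
        assert event_f1(det_blink, truth.blinks) == 1.0


class TestIO:
    def test_asc_reader(self, tmp_path):
        path = tmp_path / "samples.asc"
        path.write_text("MSG 100 start\n"
                        "100.0 960.0 540.0 800.0 961.0 541.0 805.0\n"
                        "102.0 . . . 961.0 541.0 805.0\n"
                        "104.0 960.5 540.5 802.0 961.5 541.5 806.0\n")
        stream = read_asc_samples(path)
        assert len(stream) == 3
        assert np.isnan(stream.lx[1])
        assert stream.rpupil[2] == 806.0
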