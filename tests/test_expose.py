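"""Expose operation: timing, 2000 Hz traces, dose, reduction."""
import numpy as np
import pytest

import htsaxs as hx
from htsaxs.devices import RobotMethod
from htsaxs.expose import (
    TRACE_PERIOD,
    IntensityTrace,
    RunBook,
    RunDefinition,
    integrated_dose,
    normalize_profile,
    radial_average,
    read_trace,
    run_expose,
    subtract_buffer,
    trace_sample_count,
)

A1 = hx.parse_well("A1")


class TestTraceSampling:
    @pytest.mark.parametrize("duration,count", [(1.0, 2000), (0.0, 0), (0.5, 1000),
                                                (0.0005, 1), (10.0, 20000)])
    def test_printed_rate_forces_count(self, duration, count):
        assert trace_sample_count(duration) == count

    def test_negative_duration_rejected(self):
        with pytest.raises(hx.ValidationError):
            trace_sample_count(-0.1)


def constant_trace(value=2.0, span=1.0, t0=0.0, window=None):
    n = trace_sample_count(span)
    samples = np.full((n, 3), float(value))
    window = window or (t0, t0 + span)
    return IntensityTrace(sample_period=TRACE_PERIOD, t0=t0, samples=samples,
                          shutter_window=window)


class TestIntegratedDose:
    def test_rectangle(self):
        trace = constant_trace(2.0, span=1.0)
        assert integrated_dose(trace, "I_zero", (0.0, 0.5)) == pytest.approx(1.0)

    def test_empty_window_is_zero(self):
        trace = constant_trace(2.0, span=1.0)
        assert integrated_dose(trace, "I_zero", (0.3, 0.3)) == 0.0

    def test_drifted_trace_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        n = trace_sample_count(1.0)
        samples = rng.uniform(900, 1100, (n, 3))
        trace = IntensityTrace(TRACE_PERIOD, 0.0, samples, (0.1, 0.9))
        # independent oracle: explicit python loop over the sample list
        expected = 0.0
        for i in range(n):
            t = i * TRACE_PERIOD
            if 0.1 <= t < 0.9:
                expected += samples[i, 1] * TRACE_PERIOD
        got = integrated_dose(trace, "I_zero", (0.1, 0.9))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_window_outside_trace_rejected(self):
        trace = constant_trace(2.0, span=1.0)
        with pytest.raises(hx.ValidationError):
            integrated_dose(trace, "I_zero", (0.5, 1.5))

    def test_invariant_to_padding_outside_window(self):
        # same channel values inside the window, different padding around it
        window = (0.1, 0.6)
        short = constant_trace(3.0, span=0.7, t0=0.0, window=window)
        padded = constant_trace(3.0, span=2.0, t0=-0.5, window=window)
        assert integrated_dose(short, "I_mono", window) == pytest.approx(
            integrated_dose(padded, "I_mono", window), abs=1e-12
        )


class TestReduction:
    def test_normalize_is_elementwise_division_by_izero_dose(self):
        trace = constant_trace(4.0, span=0.5)
        profile = np.array([2.0, 4.0, 8.0])
        dose = 4.0 * 0.5
        np.testing.assert_allclose(normalize_profile(profile, trace), profile / dose)

    def test_zero_dose_rejected(self):
        trace = constant_trace(0.0, span=0.5)
        with pytest.raises(hx.ValidationError):
            normalize_profile(np.ones(3), trace)

    def test_subtract_identity_and_mismatch(self):
        p = np.arange(5.0)
        assert not subtract_buffer(p, p).any()
        with pytest.raises(hx.ValidationError):
            subtract_buffer(p, np.arange(4.0))

    def test_radial_average_uniform(self):
        prof = radial_average(np.full((33, 33), 5.0))
        np.testing.assert_allclose(prof, 5.0)

    def test_radial_average_single_bright_pixel(self):
        img = np.zeros((33, 33))
        img[16, 26] = 99.0  # radius 10 from the centre
        prof = radial_average(img)
        assert prof[10] > 0
        assert np.count_nonzero(prof) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_radial_average_matches_annulus_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 100, (21, 21))
        cx = cy = 10.0
        prof = radial_average(img, center=(cx, cy))
        # brute force: collect pixels per integer-radius annulus
        rings = {}
        for y in range(21):
            for x in range(21):
                k = int(np.floor(np.hypot(x - cx, y - cy)))
                rings.setdefault(k, []).append(img[y, x])
        for k, vals in rings.items():
            assert prof[k] == pytest.approx(sum(vals) / len(vals), abs=1e-9)

    def test_center_outside_image_rejected(self):
        with pytest.raises(hx.ValidationError):
            radial_average(np.zeros((10, 10)), center=(20.0, 5.0))


class TestRunExpose:
    def test_three_exposures_exact_shutter_durations(self, loaded_beamline, tmp_path):
        run = RunDefinition(prefix="lys", directory=str(tmp_path), well=A1)
        records = run_expose([0.5, 5.0, 0.5], run, loaded_beamline)
        assert len(records) == 3
        intervals = loaded_beamline.shutter.open_intervals()
        # exact on the simulated clock: zero discrepancy at tick resolution
        tick = loaded_beamline.clock.RESOLUTION
        assert [round((b - a) / tick) for a, b in intervals] == [
            round(t / tick) for t in (0.5, 5.0, 0.5)
        ]
        # the trace's shutter window matches the transition log exactly
        for rec, interval in zip(records, intervals):
            assert rec.trace.shutter_window == interval
            assert rec.exposure_time == interval[1] - interval[0]

    def test_six_exposure_times_rejected(self, loaded_beamline, tmp_path):
        run = RunDefinition(prefix="x", directory=str(tmp_path), well=A1)
        with pytest.raises(hx.ValidationError):
            run_expose([1.0] * 6, run, loaded_beamline)
        with pytest.raises(hx.ValidationError):
            run_expose([], run, loaded_beamline)
        with pytest.raises(hx.ValidationError):
            run_expose([1.0, -0.5], run, loaded_beamline)

    def test_one_second_exposure_writes_2000_window_rows(self, loaded_beamline, tmp_path):
        run = RunDefinition(prefix="t", directory=str(tmp_path), well=A1)
        rec = run_expose([1.0], run, loaded_beamline)[0]
        trace = read_trace(rec.trace_path)
        assert int(trace.shutter_mask().sum()) == 2000
        # padded span: shutter window plus trace_pad on each side
        pad = loaded_beamline.config.trace_pad
        assert len(trace.samples) == trace_sample_count(1.0 + 2 * pad)

    def test_snapshot_taken_before_each_exposure(self, loaded_beamline, tmp_path):
        run = RunDefinition(prefix="s", directory=str(tmp_path), well=A1)
        records = run_expose([0.5, 0.5, 0.5], run, loaded_beamline)
        snaps = {rec.snapshot_path for rec in records}
        assert len(snaps) == 3
        for rec in records:
            assert rec.bubble is not None
            assert rec.bubble.frame_path == rec.snapshot_path

    def test_beam_dump_mid_list_still_produces_all_records(self, quiet_config, tmp_path):
        quiet_config.beam.dump_schedule = ((31.0, 10.0),)
        bl = hx.Beamline(quiet_config, seed=0)
        bl.robot.execute(RobotMethod.LOAD_SAMPLE, well=A1)  # clock -> 30 s
        run = RunDefinition(prefix="d", directory=str(tmp_path), well=A1)
        records = run_expose([0.5, 5.0, 0.5], run, bl)
        assert len(records) == 3
        # every shutter-open interval avoids the dump entirely
        for a, b in bl.shutter.open_intervals():
            assert bl.beam.next_conflict(a, b) is None
        assert all(r.integrated_dose["I_zero"] > 0 for r in records)

    def test_normalization_scale_invariance(self, tmp_path):
        def normalized(nominal):
            cfg = hx.SimulationConfig()
            cfg.detector.readout_noise_sd = 0.0
            cfg.detector.readout_offset = 0.0
            cfg.robot.p_bubble = 0.0
            cfg.beam.nominal_intensity = nominal
            bl = hx.Beamline(cfg, seed=0)
            bl.robot.execute(RobotMethod.LOAD_SAMPLE, well=A1)
            run = RunDefinition(prefix=f"n{int(nominal)}", directory=str(tmp_path),
                                well=A1)
            rec = run_expose([1.0], run, bl)[0]
            return normalize_profile(radial_average(rec.image), rec.trace)

        np.testing.assert_allclose(normalized(1000.0), normalized(2000.0),
                                   rtol=0, atol=1e-9)

    def test_normalization_suppresses_drift_tenfold(self, quiet_config, tmp_path):
        quiet_config.beam.drift_amplitude = 0.01
        bl = hx.Beamline(quiet_config, seed=0)
        bl.robot.execute(RobotMethod.LOAD_SAMPLE, well=A1)
        run = RunDefinition(prefix="dr", directory=str(tmp_path), well=A1)
        recs = run_expose([1.0, 1.0], run, bl)
        raw = [radial_average(r.image) for r in recs]
        norm = [normalize_profile(p, r.trace) for p, r in zip(raw, recs)]
        raw_dev = np.max(np.abs(raw[0] / raw[1] - 1))
        norm_dev = np.max(np.abs(norm[0] / norm[1] - 1))
        assert raw_dev > 1e-4  # drift is visible before normalization
        assert norm_dev <= raw_dev / 10

    def test_buffer_carryover_control_after_wash(self, quiet_config, tmp_path):
        # sample, wash, then two buffers: their normalized profiles agree
        bl = hx.Beamline(quiet_config, seed=0)
        robot = bl.robot

        def buffer_profile(tag):
            robot.execute(RobotMethod.LOAD_WATER)
            run = RunDefinition(prefix=tag, directory=str(tmp_path))
            rec = run_expose([1.0], run, bl)[0]
            robot.execute(RobotMethod.EMPTY_TO_GARBAGE)
            return normalize_profile(radial_average(rec.image), rec.trace)

        robot.execute(RobotMethod.LOAD_SAMPLE, well=A1)
        run = RunDefinition(prefix="smp", directory=str(tmp_path), well=A1)
        rec_s = run_expose([1.0], run, bl)[0]
        robot.execute(RobotMethod.EMPTY_TO_WELL, well=A1)
        robot.execute(RobotMethod.WASH_WATER)  # zero-contamination wash
        b1 = buffer_profile("buf1")
        robot.execute(RobotMethod.WASH_WATER)
        b2 = buffer_profile("buf2")
        diff = subtract_buffer(b1, b2)
        sample = normalize_profile(radial_average(rec_s.image), rec_s.trace)
        signal = np.max(np.abs(subtract_buffer(sample, b1)))
        assert np.max(np.abs(diff)) <= 1e-12 * max(signal, 1.0)

    def test_trace_file_round_trip(self, loaded_beamline, tmp_path):
        run = RunDefinition(prefix="rt", directory=str(tmp_path), well=A1)
        rec = run_expose([0.5], run, loaded_beamline)[0]
        trace = read_trace(rec.trace_path)
        dose_file = integrated_dose(trace, "I_zero", trace.shutter_window)
        assert dose_file == pytest.approx(rec.integrated_dose["I_zero"], rel=1e-5)

    def test_determinism_same_seed_identical_records(self, quiet_config, tmp_path):
        def one(tag):
            cfg = hx.SimulationConfig()
            cfg.robot.p_bubble = 0.5
            bl = hx.Beamline(cfg, seed=11)
            bl.robot.execute(RobotMethod.LOAD_SAMPLE, well=A1)
            d = tmp_path / tag
            run = RunDefinition(prefix="det", directory=str(d), well=A1)
            return [r.key() for r in run_expose([0.5, 0.5], run, bl)]

        assert one("a") == one("b")


class TestRunBook:
    def test_default_sixteen_run_tabs(self):
        book = RunBook()
        for _ in range(16):
            book.add(RunDefinition())
        with pytest.raises(hx.ValidationError):
            book.add(RunDefinition())

    def test_capacity_is_configurable(self):
        book = RunBook(max_tabs=2)
        book.add(RunDefinition())
        book.add(RunDefinition())
        with pytest.raises(hx.ValidationError):
            book.add(RunDefinition())
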