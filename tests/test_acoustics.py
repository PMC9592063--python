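import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emg2prosody.acoustics import (
    CalibrationInfo,
    PitchParams,
    calibrate_spl,
    extract_f0,
    extract_intensity,
    frame_targets,
    hz_to_semitones,
    semitones_to_hz,
    uncalibrate_spl,
)
from emg2prosody.signals import Contour, SignalTrack

from .conftest import make_pulse_train


def st_error(f_est, f_true):
    return 12.0 * np.log2(f_est / f_true)


class TestExtractF0:
    def test_pulse_train_120(self, pulse_train_120):
        contour = extract_f0(pulse_train_120)
        v = contour.defined_values()
        assert v.size > 0
        assert abs(st_error(np.median(v), 120.0)) < 0.1

    def test_silence_all_undefined(self):
        audio = SignalTrack(np.zeros(44100), 44100.0)
        assert extract_f0(audio).n_defined == 0

    def test_pure_sine_no_octave_errors(self):
        t = np.arange(0, 1.0, 1 / 44100)
        audio = SignalTrack(0.5 * np.sin(2 * np.pi * 200.0 * t), 44100.0)
        v = extract_f0(audio).defined_values()
        assert abs(st_error(np.median(v), 200.0)) < 0.1
        # nothing at the octave below (100) or above (400)
        assert not np.any(np.abs(st_error(v, 200.0)) > 6.0)

    def test_too_short_input_empty(self):
        audio = SignalTrack(np.zeros(100), 44100.0)
        assert len(extract_f0(audio)) == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            extract_f0(SignalTrack(np.zeros(4000), 1000.0))

    def test_contour_grid_is_uniform(self, pulse_train_120):
        params = PitchParams()
        contour = extract_f0(pulse_train_120, params)
        steps = np.diff(contour.times)
        assert np.allclose(steps, params.time_step, atol=1e-12)

    def test_values_within_range(self, pulse_train_120):
        params = PitchParams()
        v = extract_f0(pulse_train_120, params).defined_values()
        assert np.all((v >= params.f_min) & (v <= params.f_max))


class TestPitchParams:
    def test_default_time_step(self):
        assert PitchParams().time_step == pytest.approx(0.75 / 65.0)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            PitchParams(f_min=500.0, f_max=100.0)


class TestExtractIntensity:
    def test_amplitude_doubling_is_6dB(self):
        t = np.arange(0, 2.0, 1 / 44100)
        base = np.sin(2 * np.pi * 220.0 * t)
        i1 = extract_intensity(SignalTrack(0.2 * base, 44100.0))
        i2 = extract_intensity(SignalTrack(0.4 * base, 44100.0))
        mid = slice(10, len(i1) - 10)
        diff = i2.values[mid] - i1.values[mid]
        assert np.mean(diff) == pytest.approx(6.02, abs=0.05)

    def test_constant_sine_plateau_flat(self):
        t = np.arange(0, 2.0, 1 / 44100)
        c = extract_intensity(SignalTrack(0.3 * np.sin(2 * np.pi * 220.0 * t), 44100.0))
        mid = slice(10, len(c) - 10)
        assert np.std(c.values[mid]) < 0.1

    def test_step_transition_width(self):
        fs = 44100.0
        t = np.arange(0, 2.0, 1 / fs)
        amp = np.where(t < 1.0, 0.02, 0.2)
        c = extract_intensity(SignalTrack(amp * np.sin(2 * np.pi * 220.0 * t), fs))
        early = c.values[(c.times > 0.5) & (c.times < 0.8)].mean()
        late = c.values[(c.times > 1.2) & (c.times < 1.5)].mean()
        assert late - early == pytest.approx(20.0, abs=0.1)
        win_dur = 3.2 / 65.0
        in_transition = (c.times > 1.0 - win_dur) & (c.times < 1.0 + win_dur)
        trans_vals = c.values[in_transition]
        assert trans_vals.min() < early + 1.0 and trans_vals.max() > late - 1.0
        # outside one window duration the contour has settled
        settled = c.values[(c.times > 1.0 + win_dur) & (c.times < 1.5)]
        assert np.all(np.abs(settled - late) < 0.5)

    def test_all_zero_input_finite(self):
        c = extract_intensity(SignalTrack(np.zeros(44100 * 2), 44100.0))
        assert np.all(np.isfinite(c.values))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_intensity(SignalTrack(np.zeros(0), 44100.0))


class TestCalibration:
    def test_zero_offset_identity(self):
        c = Contour(np.arange(5) * 0.1, np.arange(5.0), "dB")
        cal = CalibrationInfo(meter_reading=70.0, measured_level=70.0)
        out = calibrate_spl(c, cal)
        assert np.allclose(out.values, c.values)
        assert out.unit == "dB SPL"

    def test_additive_shift(self):
        c = Contour(np.arange(5) * 0.1, np.full(5, 70.0), "dB")
        cal = CalibrationInfo(meter_reading=82.0, measured_level=70.0)
        assert np.allclose(calibrate_spl(c, cal).values, 82.0)

    def test_round_trip(self):
        c = Contour(np.arange(5) * 0.1, np.linspace(50, 80, 5), "dB")
        cal = CalibrationInfo(meter_reading=91.3, measured_level=74.2)
        back = uncalibrate_spl(calibrate_spl(c, cal), cal)
        assert np.allclose(back.values, c.values, atol=1e-12)

    def test_unit_mismatch_rejected(self):
        c = Contour(np.arange(3) * 0.1, np.zeros(3), "ST")
        cal = CalibrationInfo(meter_reading=80.0, measured_level=70.0)
        with pytest.raises(ValueError):
            calibrate_spl(c, cal)


class TestSemitones:
    def test_reference_is_zero(self):
        assert hz_to_semitones(90.0, 90.0) == 0.0

    def test_octave_is_12(self):
        assert hz_to_semitones(180.0, 90.0) == pytest.approx(12.0, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hz_to_semitones(-5.0, 90.0)
        with pytest.raises(ValueError):
            hz_to_semitones(100.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_round_trip(self, f):
        assert semitones_to_hz(hz_to_semitones(f, 90.0), 90.0) == pytest.approx(
            f, rel=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=1e-3, max_value=1e4),
        st.floats(min_value=1e-3, max_value=1e4),
    )
    def test_strictly_increasing(self, a, b):
        if a != b:
            lo, hi = min(a, b), max(a, b)
            assert hz_to_semitones(lo, 90.0) < hz_to_semitones(hi, 90.0)


class TestFrameTargets:
    def _contour(self, n=100, dt=0.01, value=5.0):
        return Contour(np.arange(n) * dt, np.full(n, value), unit="Hz")

    def test_frame_count(self):
        out = frame_targets(self._contour(), 0.040, 0.020)
        assert len(out) == 49

    def test_constant_contour_means(self):
        out = frame_targets(self._contour(value=7.5), 0.040, 0.020)
        assert np.allclose(out.defined_values(), 7.5)

    def test_half_defined_mask(self):
        c = self._contour()
        vals = c.values.copy()
        vals[50:] = np.nan
        c = Contour(c.times, vals, "Hz")
        out = frame_targets(c, 0.040, 0.020, min_coverage=0.5)
        # frames fully inside the undefined second half must be dropped
        defined_expected = np.array(
            [
                np.sum(~np.isnan(vals[np.round(np.arange(k * 0.02, k * 0.02 + 0.04, 0.01) * 100).astype(int)[:4]])) >= 2
                for k in range(49)
            ]
        )
        assert out.defined.sum() == defined_expected.sum()
        assert not out.defined[-5:].any()

    def test_empty_contour(self):
        empty = Contour(np.zeros(0), np.zeros(0), "Hz", np.zeros(0, bool))
        assert len(frame_targets(empty, 0.04, 0.02)) == 0

    def test_frame_times_on_step_grid(self):
        out = frame_targets(self._contour(), 0.040, 0.020)
        assert np.allclose(out.times, 0.020 * np.arange(49), atol=1e-12)

    def test_rejects_step_above_frame(self):
        with pytest.raises(ValueError):
            frame_targets(self._contour(), 0.020, 0.040)


class TestTrackerSweepSmall:
    """Coarse 5-point version of the acceptance sweep for fast feedback."""

    @pytest.mark.parametrize("f0", [65.0, 110.0, 200.0, 350.0, 475.0])
    def test_tracking_error(self, f0):
        audio = make_pulse_train(f0, duration=1.0, seed=int(f0))
        v = extract_f0(audio).defined_values()
        errs = np.abs(st_error(v, f0))
        assert np.median(errs) < 0.1
        assert not np.any(errs > 6.0)  # no octave errors
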