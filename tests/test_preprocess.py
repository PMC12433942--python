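"""Envelope construction, MVC normalization and phase time-normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from emgsyn import (CANONICAL_MUSCLES, EmgRecording, ValidationError,
                    build_envelope, normalize_mvc, read_recording,
                    segment_phases, write_recording)
from emgsyn.preprocess import (EDGE_GUARD_S, EnvelopeExtractor,
                               resample_phase)

FS = 2000.0


def _recording(signal, fs=FS, mvc=None, events=None):
    n = signal.shape[1]
    return EmgRecording(
        signal=signal, fs=fs, muscle_labels=CANONICAL_MUSCLES,
        mvc=np.ones(14) if mvc is None else mvc,
        events=events or {"touchdown": 0, "ball_contact": n // 2, "swing_end": n - 1},
    )


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path, model_r3):
        from emgsyn import synthesize_subject
        rec = synthesize_subject(model_r3, noise_sd=0.05, seed=3)
        write_recording(rec, tmp_path / "r.csv", tmp_path / "r.json")
        back = read_recording(tmp_path / "r.csv", tmp_path / "r.json")
        assert back.muscle_labels == tuple(CANONICAL_MUSCLES)
        assert back.events == rec.events
        assert back.signal_kind == "envelope"
        np.testing.assert_allclose(back.signal, rec.signal, rtol=1e-6)

    def test_missing_channel_names_absent_label(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame(np.zeros((10, 13)), columns=list(CANONICAL_MUSCLES[:13]))
        df.to_csv(tmp_path / "bad.csv", index=False)
        (tmp_path / "bad.json").write_text(
            '{"fs": 2000, "mvc": {}, "events": {"touchdown": 0, "ball_contact": 4, "swing_end": 9}}')
        with pytest.raises(ValidationError, match="L-GL"):
            read_recording(tmp_path / "bad.csv", tmp_path / "bad.json")

    def test_unordered_events_rejected(self):
        with pytest.raises(ValidationError, match="touchdown < ball_contact"):
            _recording(np.ones((14, 100)),
                       events={"touchdown": 50, "ball_contact": 10, "swing_end": 99})

    def test_nonpositive_mvc_rejected(self):
        mvc = np.ones(14)
        mvc[5] = 0.0
        with pytest.raises(ValidationError, match="R-TA"):
            _recording(np.ones((14, 100)), mvc=mvc)


class TestEnvelope:
    def test_zero_signal_gives_zero_envelope(self):
        env = build_envelope(_recording(np.zeros((14, 2000))))
        np.testing.assert_array_equal(env, 0.0)

    def test_dc_offset_removed(self):
        """High-pass stage kills a constant offset (outside edge transients)."""
        offset = 3.7
        env = build_envelope(_recording(np.full((14, 4000), offset)))
        guard = int(EDGE_GUARD_S * FS)
        assert np.all(env[:, guard:-guard] < 1e-3 * offset)

    def test_sine_envelope_mean_is_rectified_mean(self):
        """A 100 Hz unit sine has interior envelope mean ≈ 2/π, the mean of
        |sin| by direct numerical integration."""
        t = np.arange(8000) / FS
        sig = np.sin(2 * np.pi * 100 * t)[None, :].repeat(14, axis=0)
        env = build_envelope(_recording(sig))
        guard = int(EDGE_GUARD_S * FS)
        interior = env[0, guard:-guard]
        oracle = np.trapezoid(np.abs(np.sin(np.linspace(0, np.pi, 20001))),
                              dx=np.pi / 20000) / np.pi
        assert oracle == pytest.approx(2 / np.pi, rel=1e-6)
        assert interior.mean() == pytest.approx(2 / np.pi, rel=0.02)

    def test_matches_independent_filter_implementation(self, rng):
        """Same chain built from transfer-function filtfilt calls."""
        x = rng.normal(size=(3, 4000))
        ext = EnvelopeExtractor(fs=FS).fit()
        ours = ext.transform(x)
        b_hp, a_hp = sps.butter(4, 50, "highpass", fs=FS)
        b_lp, a_lp = sps.butter(4, 20, "lowpass", fs=FS)
        ref = sps.filtfilt(b_lp, a_lp, np.abs(sps.filtfilt(b_hp, a_hp, x, axis=1)), axis=1)
        guard = int(EDGE_GUARD_S * FS)
        np.testing.assert_allclose(ours[:, guard:-guard],
                                   np.clip(ref, 0, None)[:, guard:-guard],
                                   atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            EnvelopeExtractor(fs=100.0, hp_cut=50.0).fit()

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=(2, 3000))
        ext = EnvelopeExtractor(fs=FS).fit()
        np.testing.assert_allclose(ext.transform(3.5 * x), 3.5 * ext.transform(x),
                                   rtol=1e-9, atol=1e-12)

    def test_envelope_nonnegative(self, rng):
        x = rng.normal(size=(4, 3000)) * rng.uniform(0.1, 5, size=(4, 1))
        assert np.all(build_envelope(_recording(np.vstack([x, x, x, x[:2]]))) >= 0)


class TestMvcNormalization:
    def test_row_at_its_mvc_becomes_one(self):
        env = np.full((14, 50), 2.5)
        out = normalize_mvc(env, np.full(14, 2.5))
        np.testing.assert_array_equal(out, 1.0)

    def test_half_mvc_becomes_half(self):
        out = normalize_mvc(np.full((14, 10), 1.0), np.full(14, 2.0))
        np.testing.assert_array_equal(out, 0.5)

    def test_zero_mvc_names_channel(self):
        mvc = np.ones(14)
        mvc[3] = 0.0
        with pytest.raises(ValidationError, match="R-BF"):
            normalize_mvc(np.ones((14, 5)), mvc, CANONICAL_MUSCLES)


class TestPhaseNormalization:
    def test_linear_ramp_preserved(self):
        ramp = np.linspace(0.0, 1.0, 173)[None, :]
        out = resample_phase(ramp, 100)
        np.testing.assert_allclose(out, np.linspace(0, 1, 100)[None, :], atol=1e-9)

    @pytest.mark.parametrize("n_tc,n_sw", [(57, 211), (1000, 700), (2, 2)])
    def test_output_length_is_n_points(self, n_tc, n_sw):
        n = n_tc + n_sw + 1
        env = np.abs(np.sin(np.linspace(0, 7, n)))[None, :].repeat(14, axis=0)
        events = {"touchdown": 0, "ball_contact": n_tc, "swing_end": n - 1}
        mat = segment_phases(env, events, n_points=100)
        assert mat.values.shape == (14, 200)
        assert mat.phase_bounds == {"TC": (0, 100), "SW": (100, 200)}

    def test_quadratic_matches_closed_form(self):
        """Resampled parabola equals analytic evaluation at the 100
        equidistant relative times of the phase."""
        n_in = 401
        x = np.linspace(0.0, 1.0, n_in)
        env = (2.0 * x**2 + 0.5)[None, :]
        events = {"touchdown": 0, "ball_contact": n_in - 1, "swing_end": n_in}
        out = resample_phase(env[:, :n_in], 100)
        x_exp = np.linspace(0.0, 1.0, 100)
        np.testing.assert_allclose(out[0], 2.0 * x_exp**2 + 0.5, atol=1e-4)

    def test_idempotent_on_already_normalized_phase(self, rng):
        y = rng.uniform(size=(14, 100))
        np.testing.assert_allclose(resample_phase(y, 100), y, atol=1e-12)

    def test_zero_duration_phase_rejected(self):
        env = np.ones((14, 100))
        with pytest.raises(ValidationError, match="duration"):
            segment_phases(env, {"touchdown": 10, "ball_contact": 10, "swing_end": 99})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=50), st.integers(min_value=0, max_value=2**31 - 1))
def test_resampling_stays_within_input_range(n_points, seed):
    """Linear interpolation cannot overshoot the input envelope range."""
    y = np.random.default_rng(seed).uniform(0, 3, size=(2, 37))
    out = resample_phase(y, n_points)
    assert out.min() >= y.min() - 1e-12 and out.max() <= y.max() + 1e-12
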