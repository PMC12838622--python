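import numpy as np
import pytest

from fatiguekit.emg import bandpass_emg, emg_at_median, emg_envelope, emg_ft_slope
from fatiguekit.force import fatigue_slope
from fatiguekit.io import TimeSeries, build_cue_schedule

RATE = 2048.0


def _tone(freq, duration=4.0, amplitude=1.0, rate=RATE, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return TimeSeries(0.0, rate, amplitude * np.sin(2 * np.pi * freq * t + phase))


def _interior(values, rate=RATE, guard_s=0.25):
    g = int(guard_s * rate)
    return values[g:-g]


def _rms(v):
    return float(np.sqrt(np.mean(v**2)))


class TestBandpass:
    def test_5hz_attenuated_20db(self):
        tone = _tone(5.0)
        out = bandpass_emg(tone)
        ratio = _rms(_interior(out.values)) / _rms(_interior(tone.values))
        assert 20 * np.log10(ratio) <= -20.0

    def test_100hz_passband_within_1db(self):
        tone = _tone(100.0)
        out = bandpass_emg(tone)
        gain_db = 20 * np.log10(_rms(_interior(out.values)) / _rms(_interior(tone.values)))
        assert abs(gain_db) <= 1.0

    def test_dc_removed(self):
        ts = TimeSeries(0.0, RATE, np.full(int(2 * RATE), 5.0))
        out = bandpass_emg(ts)
        assert np.max(np.abs(_interior(out.values))) < 1e-6 * 5.0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            bandpass_emg(TimeSeries(0.0, 800.0, np.zeros(100) + 1.0), high=500.0)

    def test_length_preserved(self, rng):
        ts = TimeSeries(0.0, RATE, rng.normal(size=4096))
        assert bandpass_emg(ts).n == 4096

    def test_passband_idempotent_within_2db(self):
        tone = _tone(100.0)
        once = bandpass_emg(tone)
        twice = bandpass_emg(once)
        change_db = 20 * np.log10(_rms(_interior(twice.values)) / _rms(_interior(once.values)))
        assert abs(change_db) < 2.0


class TestEnvelope:
    def test_zero_input(self):
        env = emg_envelope(TimeSeries(0.0, RATE, np.zeros(1000)))
        assert np.all(env.series.values == 0.0)

    def test_sinusoid_amplitude(self):
        amp = 3.7
        env = emg_envelope(_tone(150.0, amplitude=amp))
        inner = _interior(env.series.values)
        assert np.all(np.abs(inner - amp) < 0.02 * amp)

    def test_phase_invariance(self):
        a = emg_envelope(_tone(150.0, phase=0.0)).series.values
        b = emg_envelope(_tone(150.0, phase=1.3)).series.values
        assert np.allclose(_interior(a), _interior(b), atol=0.01)

    def test_linear_amplitude_scaling(self):
        e1 = emg_envelope(_tone(150.0, amplitude=1.0)).series.values
        e2 = emg_envelope(_tone(150.0, amplitude=2.5)).series.values
        np.testing.assert_allclose(e2, 2.5 * e1, rtol=1e-9)

    @pytest.mark.parametrize("method", ["hilbert", "rectify_lowpass"])
    def test_gated_carrier_tracks_gate(self, method):
        """Envelope of a square-gated 150 Hz carrier follows the gate within 5%
        of the carrier amplitude, excluding 50 ms around each transition."""
        amp, rate = 2.0, RATE
        duration, period = 8.0, 2.0
        t = np.arange(int(duration * rate)) / rate
        gate = ((t % period) < period / 2).astype(float)
        carrier = np.sin(2 * np.pi * 150.0 * t)
        env = emg_envelope(TimeSeries(0.0, rate, amp * gate * carrier), method=method)
        # rectified sine has mean 2A/pi; compare Hilbert to A, rectified to its own scale
        expect = amp * gate if method == "hilbert" else amp * gate * 2 / np.pi
        keep = np.ones(t.size, dtype=bool)
        for edge in np.arange(0, duration + 1e-9, period / 2):
            keep &= np.abs(t - edge) > 0.05
        keep[: int(0.1 * rate)] = keep[-int(0.1 * rate) :] = False
        mae = np.mean(np.abs(env.series.values[keep] - expect[keep]))
        assert mae < 0.05 * amp


class TestFtSlope:
    def _gated_envelope(self, n_cycles, scale):
        """Piecewise-constant envelope: value scale(k) during contraction k."""
        rate = 256.0
        sched = build_cue_schedule(n_cycles, 1.0, 1.0)
        n = int(sched.task_duration * rate)
        t = np.arange(n) / rate
        v = np.zeros(n)
        for k, (s, e) in enumerate(sched.cycles):
            v[(t >= s) & (t < e)] = scale(k)
        return emg_envelope(TimeSeries(0.0, rate, v), method="hilbert"), sched

    def test_constant_envelope_zero_slope(self):
        rate = 256.0
        sched = build_cue_schedule(20, 1.0, 1.0)
        ts = TimeSeries(0.0, rate, np.full(int(sched.task_duration * rate), 3.0))
        from fatiguekit.emg import EnvelopeTrace

        est = emg_ft_slope(EnvelopeTrace(ts, method="precomputed"), sched, discard_first=5)
        assert est.beta == pytest.approx(0.0, abs=1e-12)

    def test_linear_decay_recovered(self):
        """Per-contraction envelope scaled by (1 - 0.001 k) gives the matching
        negative AUC slope on noiseless input."""
        from fatiguekit.emg import EnvelopeTrace

        rate, n_cycles = 256.0, 60
        sched = build_cue_schedule(n_cycles, 1.0, 1.0)
        n = int(sched.task_duration * rate)
        t = np.arange(n) / rate
        v = np.zeros(n)
        for k, (s, e) in enumerate(sched.cycles):
            v[(t >= s) & (t < e)] = 1.0 - 0.001 * k
        env = EnvelopeTrace(TimeSeries(0.0, rate, v), method="precomputed")
        est = emg_ft_slope(env, sched, discard_first=10)
        # analytic: AUC_k = (1 - 0.001 k) * quadrature area of the unit gate
        from fatiguekit.force import contraction_auc, segment_contractions

        unit = np.zeros(n)
        for s, e in sched.cycles:
            unit[(t >= s) & (t < e)] = 1.0
        unit_aucs = [
            contraction_auc(seg)
            for seg in segment_contractions(TimeSeries(0.0, rate, unit), sched)
        ]
        analytic = fatigue_slope(
            [(1.0 - 0.001 * k) * a for k, a in enumerate(unit_aucs)], discard_first=10
        )
        assert est.beta < 0
        assert abs(est.beta - analytic.beta) < 1e-6

    def test_full_protocol_has_260_points(self):
        from fatiguekit.emg import EnvelopeTrace

        rate = 64.0
        sched = build_cue_schedule(270, 1.0, 1.0)
        ts = TimeSeries(0.0, rate, np.abs(np.random.default_rng(3).normal(size=int(540 * rate))))
        est = emg_ft_slope(EnvelopeTrace(ts, method="precomputed"), sched)
        assert est.n_points == 260

    def test_shares_pipeline_with_force_slope(self):
        """emg_ft_slope equals fatigue_slope applied to the envelope's AUCs."""
        from fatiguekit.emg import EnvelopeTrace
        from fatiguekit.force import contraction_auc, segment_contractions

        rng = np.random.default_rng(9)
        rate = 128.0
        sched = build_cue_schedule(30, 1.0, 1.0)
        ts = TimeSeries(0.0, rate, np.abs(rng.normal(size=int(60 * rate))))
        env = EnvelopeTrace(ts, method="precomputed")
        direct = emg_ft_slope(env, sched)
        aucs = [contraction_auc(s) for s in segment_contractions(ts, sched)]
        assert direct.beta == fatigue_slope(aucs).beta


class TestAtMedian:
    def _env(self, values, rate=100.0):
        from fatiguekit.emg import EnvelopeTrace

        return EnvelopeTrace(TimeSeries(0.0, rate, values), method="precomputed")

    def test_constant(self):
        env = self._env(np.full(1000, 2.5))
        assert emg_at_median(env, 1.0, 9.0) == 2.5

    def test_outlier_robust(self):
        env = self._env(np.array([1.0, 2.0, 3.0, 4.0, 100.0]), rate=1.0)
        assert emg_at_median(env, 0.0, 4.0) == 3.0

    def test_gated_carrier_median_matches_sort_oracle(self, rng):
        values = np.abs(rng.normal(size=5000)) * (rng.uniform(size=5000) > 0.5)
        env = self._env(values, rate=500.0)
        got = emg_at_median(env, 1.0, 9.0)
        window = env.series.slice_time(1.0, 9.0).values
        oracle = float(np.sort(window)[window.size // 2]) if window.size % 2 else float(
            np.mean(np.sort(window)[window.size // 2 - 1 : window.size // 2 + 1])
        )
        assert got == pytest.approx(oracle)

    def test_empty_window_rejected(self):
        env = self._env(np.ones(100))
        with pytest.raises(ValueError):
            emg_at_median(env, 0.5, 0.5)
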