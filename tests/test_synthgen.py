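"""Generator contracts: breathing shape, event/PB injection, radar modulation."""

import numpy as np
import pytest
from scipy.signal import hilbert

import respiradar as rr
from respiradar.synthgen import MAX_DISPLACEMENT_MM


def _strict_maxima_count(x):
    """Independent oracle: count strict interior local maxima."""
    return int(np.sum((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])))


class TestSimulateRespiration:
    def test_zero_amplitude_gives_flat_line(self):
        w = rr.simulate_respiration(
            rr.BreathProfile(amplitude_mm=0.0), 30.0, 20.0, seed=0
        )
        assert np.all(w.samples == 0.0)

    def test_breath_count_matches_rate_without_jitter(self):
        # 15 bpm for 60 s -> exactly 15 raised-cosine peaks
        prof = rr.BreathProfile(rate_bpm=15.0, rate_jitter=0.0, amplitude_jitter=0.0)
        w = rr.simulate_respiration(prof, 60.0, 20.0, seed=0)
        assert _strict_maxima_count(w.samples) == 15

    @pytest.mark.parametrize("amp", [1.0, 5.0, 12.0])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_displacement_stays_within_physiological_range(self, amp, seed):
        prof = rr.BreathProfile(amplitude_mm=amp, amplitude_jitter=0.3)
        w = rr.simulate_respiration(prof, 300.0, 20.0, seed=seed)
        assert np.max(w.samples) - np.min(w.samples) <= MAX_DISPLACEMENT_MM + 1e-9

    def test_amplitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rr.BreathProfile(amplitude_mm=13.0)
        with pytest.raises(ValueError):
            rr.BreathProfile(amplitude_mm=-1.0)

    def test_seeded_determinism(self):
        a = rr.simulate_respiration(rr.BreathProfile(), 60.0, 20.0, seed=5)
        b = rr.simulate_respiration(rr.BreathProfile(), 60.0, 20.0, seed=5)
        assert np.array_equal(a.samples, b.samples)


class TestInjectEvents:
    def test_empty_list_is_identity(self, calm_wave):
        out, truth = rr.inject_events(calm_wave, [], seed=0)
        assert truth == []
        assert np.array_equal(out.samples, calm_wave.samples)

    def test_apnea_suppresses_envelope_to_depth(self, calm_wave):
        spec = rr.EventSpec("apnea", onset_s=30.0, duration_s=15.0,
                            depth_fraction=0.03)
        out, truth = rr.inject_events(calm_wave, [spec], seed=0)
        # peak-envelope oracle: breathing excursion (peak-to-peak) on the
        # event plateau, output vs input, must be suppressed to the depth
        sl = slice(int(33 * 20), int(42 * 20))
        ratio = np.ptp(out.samples[sl]) / np.ptp(calm_wave.samples[sl])
        assert ratio <= 0.05
        assert truth == [rr.RespiratoryEvent("apnea", 30.0, 15.0)]

    def test_overlapping_events_rejected(self, calm_wave):
        specs = [
            rr.EventSpec("apnea", 30.0, 15.0),
            rr.EventSpec("hypopnea", 40.0, 12.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            rr.inject_events(calm_wave, specs, seed=0)

    def test_truth_bookkeeping_verbatim(self, calm_wave):
        specs = [
            rr.EventSpec("apnea", 50.0, 20.0),
            rr.EventSpec("hypopnea", 200.0, 14.0, 0.4),
        ]
        _, truth = rr.inject_events(calm_wave, specs, seed=0)
        assert [(t.kind, t.onset_s, t.duration_s) for t in truth] == [
            ("apnea", 50.0, 20.0),
            ("hypopnea", 200.0, 14.0),
        ]

    def test_short_event_rejected(self):
        with pytest.raises(ValueError):
            rr.EventSpec("apnea", 10.0, 9.0)


class TestInjectPeriodicBreathing:
    def test_fewer_than_three_cycles_rejected(self):
        with pytest.raises(ValueError):
            rr.PBSpec(n_cycles=0)
        with pytest.raises(ValueError):
            rr.PBSpec(n_cycles=2)

    def test_truth_phase_durations_sum_to_cycle_length(self, calm_wave):
        spec = rr.PBSpec(n_cycles=4, cycle_length_s=40.0, apneic_fraction=0.4)
        _, ep = rr.inject_periodic_breathing(calm_wave, spec, 100.0, seed=0)
        assert ep.n_cycles == 4
        for a, v in ep.cycles:
            assert a + v == pytest.approx(40.0)

    def test_envelope_autocorrelation_peaks_at_cycle_length(self):
        # 5 cycles of exactly 40 s -> first off-zero autocorrelation peak
        # of the analytic envelope at lag 40 +- 1 s
        w = rr.simulate_respiration(rr.BreathProfile(), 400.0, 20.0, seed=2)
        spec = rr.PBSpec(n_cycles=5, cycle_length_s=40.0, apneic_fraction=0.4)
        out, _ = rr.inject_periodic_breathing(w, spec, 100.0, seed=0)
        seg = out.samples[int(100 * 20): int(300 * 20)]
        env = np.abs(hilbert(seg - seg.mean()))
        env = env - env.mean()
        ac = np.correlate(env, env, mode="full")[len(env) - 1:]
        # first peak after the zero-lag lobe decays
        lags = np.arange(len(ac)) / 20.0
        search = (lags > 20.0) & (lags < 60.0)
        lag_peak = lags[search][np.argmax(ac[search])]
        assert lag_peak == pytest.approx(40.0, abs=1.0)

    def test_episode_outside_waveform_rejected(self, calm_wave):
        spec = rr.PBSpec(n_cycles=5, cycle_length_s=40.0)
        with pytest.raises(ValueError):
            rr.inject_periodic_breathing(calm_wave, spec, 500.0, seed=0)


class TestModulateRadar:
    def test_zero_displacement_gives_constant_iq(self):
        w = rr.RespWaveform(np.zeros(200), fs=20.0)
        r = rr.modulate_radar(w, noise_sd=0.0, drift_amp=0.0, seed=0)
        assert np.ptp(r.i_samples) == 0.0
        assert np.ptp(r.q_samples) == 0.0

    def test_default_wavelength_is_24ghz_carrier(self):
        w = rr.RespWaveform(np.zeros(10), fs=20.0)
        assert rr.modulate_radar(w).wavelength_mm == 12.5

    def test_noise_free_round_trip(self):
        t = np.arange(0, 60, 1 / 20.0)
        d = 3.0 * np.sin(2 * np.pi * 0.25 * t)
        w = rr.RespWaveform(d, fs=20.0)
        rec = rr.demodulate(rr.modulate_radar(w, noise_sd=0.0, drift_amp=0.0))
        rms = np.sqrt(np.mean((rec.samples - (d - d.mean())) ** 2))
        assert rms < 1e-6


class TestSimulateNight:
    def test_byte_identical_under_seed(self):
        spec = rr.NightSpec(duration_h=0.5, event_rate_per_h=30.0, seed=3)
        w1, t1 = rr.simulate_night(spec)
        w2, t2 = rr.simulate_night(spec)
        assert np.array_equal(w1.samples, w2.samples)
        assert t1["events"] == t2["events"]
        assert t1["stages"] == t2["stages"]

    def test_truth_accounting(self):
        spec = rr.NightSpec(
            duration_h=1.0, event_rate_per_h=30.0,
            wake_blocks=((0.0, 600.0),), seed=4,
        )
        w, truth = rr.simulate_night(spec)
        assert truth["tib_h"] == pytest.approx(1.0)
        assert truth["tst_h"] == pytest.approx(1.0 - 600.0 / 3600.0)
        assert len(truth["events"]) == round(30.0 * truth["tst_h"])
        assert len(truth["stages"]) == 120
        # events only inside sleep time
        for ev in truth["events"]:
            k = int((ev.onset_s + ev.duration_s / 2) // 30.0)
            assert truth["stages"][k] == "sleep"
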