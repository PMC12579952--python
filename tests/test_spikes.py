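"""Spike pipeline: filtering, normalization, detection, artifacts, rates."""

import numpy as np
import pytest

from beetaste.spikes import (
    FiringRecord,
    SpikeEvent,
    Trace,
    bandpass_filter,
    bin_rates,
    detect_spikes,
    firing_rate,
    flag_unresponsive_sensilla,
    normalize_baseline,
    process_trace,
    remove_artifacts,
    window_spikes,
)
from beetaste.synth import EphysSimConfig, generate_grn_trace, spike_template

FS = 30000.0


def sine_trace(freq, duration=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return Trace(samples=np.sin(2 * np.pi * freq * t), sample_rate=fs)


def make_event(time, amp, width_ms=0.8, fs=FS):
    tmpl = amp * spike_template(width_ms, fs)
    half = int(round(0.002 * fs))
    h = len(tmpl) // 2
    if h > half:  # template support exceeds the snippet; trim symmetrically
        tmpl = tmpl[h - half : h + half + 1]
        h = half
    wf = np.zeros(2 * half + 1)
    wf[half - h : half + h + 1] = tmpl
    from beetaste.spikes import _waveform_width_ms

    return SpikeEvent(time=time, peak_amplitude=amp, waveform=wf,
                      width_ms=_waveform_width_ms(wf, fs))


class TestBandpass:
    def test_stopband_50hz_attenuated(self):
        out = bandpass_filter(sine_trace(50))
        assert np.sqrt(np.mean(out.samples**2)) < 0.05 * np.sqrt(0.5)

    def test_passband_500hz_preserved(self):
        out = bandpass_filter(sine_trace(500))
        assert np.sqrt(np.mean(out.samples**2)) > 0.80 * np.sqrt(0.5)

    def test_zero_trace_maps_to_zero(self):
        out = bandpass_filter(Trace(samples=np.zeros(3000), sample_rate=FS))
        assert np.allclose(out.samples, 0)

    @pytest.mark.parametrize("band", [(0, 1000), (1000, 100), (100, 20000)])
    def test_invalid_band_rejected(self, band):
        with pytest.raises(ValueError):
            bandpass_filter(sine_trace(500), *band)


class TestNormalize:
    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30000)
        a = normalize_baseline(Trace(samples=x, sample_rate=FS))
        b = normalize_baseline(Trace(samples=x + 7.0, sample_rate=FS))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-9)

    def test_linear_drift_removed(self):
        n = int(3 * FS)
        drift = np.linspace(0, 30.0, n)  # 10 mV/s over 3 s
        rng = np.random.default_rng(1)
        out = normalize_baseline(
            Trace(samples=drift + rng.normal(0, 0.1, n), sample_rate=FS)
        )
        # residual is pure noise in noise-SD units; no drift-scale values remain
        assert np.max(np.abs(out.samples)) < 0.05 * 30.0 / 0.1

    def test_zero_variance_trace_stays_zero(self):
        out = normalize_baseline(Trace(samples=np.full(3000, 5.0), sample_rate=FS))
        assert np.allclose(out.samples, 0)


class TestDetect:
    def test_recovers_injected_spikes_at_snr3(self):
        """Ten spikes at 3x noise SD, auto threshold: all ten recovered at
        the injected times within 0.2 ms, nothing else."""
        rng = np.random.default_rng(42)
        n = int(1.0 * FS)
        x = rng.normal(0, 1 / 3, n)
        tmpl = spike_template(0.8, FS)
        h = len(tmpl) // 2
        truth_idx = np.linspace(0.1, 0.9, 10) * FS
        for idx in truth_idx.astype(int):
            x[idx - h : idx + h + 1] += 1.0 * tmpl
        trace = normalize_baseline(bandpass_filter(Trace(samples=x, sample_rate=FS)))
        events = detect_spikes(trace, "auto")
        assert len(events) == 10
        det = np.array([e.time for e in events])
        assert np.all(np.abs(det - truth_idx / FS) <= 0.2e-3)

    def test_threshold_above_max_gives_empty(self):
        rng = np.random.default_rng(0)
        trace = Trace(samples=rng.normal(0, 1, 3000), sample_rate=FS)
        assert detect_spikes(trace, 1e6) == []

    def test_non_positive_threshold_rejected(self):
        trace = Trace(samples=np.zeros(3000), sample_rate=FS)
        with pytest.raises(ValueError):
            detect_spikes(trace, 0.0)

    def test_refractory_merge_keeps_larger_peak(self):
        """Two peaks 0.5 ms apart merge into one event, the larger kept."""
        x = np.zeros(3000)
        x[1500] = 8.0
        x[1500 + 15] = 6.0  # 0.5 ms later at 30 kHz
        events = detect_spikes(Trace(samples=x, sample_rate=FS), 5.0)
        assert len(events) == 1
        assert events[0].time == pytest.approx(1500 / FS)
        assert events[0].peak_amplitude == pytest.approx(8.0)


class TestWindow:
    def test_half_open_boundaries(self):
        events = [make_event(t, 5.0) for t in (0.05, 0.10, 2.09, 2.10)]
        kept = window_spikes(events)
        assert [e.time for e in kept] == [0.10, 2.09]

    def test_empty_and_identity(self):
        assert window_spikes([]) == []
        inside = [make_event(t, 5.0) for t in (0.5, 1.0, 2.0)]
        assert window_spikes(inside) == inside

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            window_spikes([], start=2.0, end=1.0)


class TestArtifacts:
    def test_identical_events_no_rejection(self):
        events = [make_event(0.2 + i * 0.01, 1.0) for i in range(100)]
        kept, counts = remove_artifacts(events, FS)
        assert len(kept) == 100
        assert counts == {"amplitude": 0, "width": 0}

    def test_single_large_amplitude_outlier_rejected(self):
        """99 events at amplitude 1.0 plus one at 10.0: the sample mean is
        1.09 and the sample SD is exactly 0.9, so the cut sits at
        1.09 + 3 * 0.9 = 3.79 — only the 10.0 event exceeds it."""
        events = [make_event(0.2 + i * 0.01, 1.0) for i in range(99)]
        events.append(make_event(0.2 + 99 * 0.01, 10.0))
        amps = np.array([e.peak_amplitude for e in events])
        cut = amps.mean() + 3 * amps.std(ddof=1)
        assert cut == pytest.approx(3.79, abs=1e-9)
        kept, counts = remove_artifacts(events, FS)
        assert counts["amplitude"] == 1
        assert all(e.peak_amplitude == 1.0 for e in kept)

    def test_width_bound_is_45_samples_at_30khz(self):
        narrow = make_event(0.2, 1.0, width_ms=0.8)
        wide = make_event(0.3, 1.0, width_ms=2.0)
        assert narrow.width_ms * 30 < 45  # below the 45-sample bound
        assert wide.width_ms * 30 > 45
        kept, counts = remove_artifacts([narrow] * 10 + [wide], FS)
        assert counts["width"] == 1
        assert len(kept) == 10


class TestRates:
    def test_uniform_events_give_count_rate(self):
        events = [make_event(t, 5.0) for t in np.linspace(0.1, 1.0999, 80)]
        assert firing_rate(events) == 80.0

    def test_no_events_zero(self):
        assert firing_rate([]) == 0.0

    def test_events_outside_first_second_ignored(self):
        events = [make_event(t, 5.0) for t in np.linspace(1.1, 2.09, 30)]
        assert firing_rate(events) == 0.0

    def test_bin_structure_and_conservation(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0.1, 2.1 - 1e-9, 200)
        events = [make_event(t, 5.0) for t in times]
        bins = bin_rates(events)
        assert len(bins) == 20
        assert bins.sum() == 200

    def test_single_event_lands_in_first_bin(self):
        bins = bin_rates([make_event(0.15, 5.0)])
        assert bins[0] == 1 and bins.sum() == 1

    def test_rate_equals_sum_of_first_ten_bins(self, snr3_sim):
        rec = process_trace(snr3_sim.trace)
        assert rec.rate_1s == rec.binned[:10].sum()


class TestPipeline:
    def test_detection_conservation(self):
        """After windowing, every detected event is either retained or
        counted in exactly one rejection tally."""
        cfg = EphysSimConfig(
            peak_rate=80, tonic_rate=25, noise_sd=1 / 3,
            n_large_artifacts=2, n_wide_artifacts=2, seed=17,
        )
        sim = generate_grn_trace(cfg)
        prepped = normalize_baseline(bandpass_filter(sim.trace))
        windowed = window_spikes(detect_spikes(prepped))
        kept, counts = remove_artifacts(windowed, cfg.sample_rate)
        assert len(windowed) == len(kept) + counts["amplitude"] + counts["width"]

    def test_recovery_sensitivity_and_precision(self):
        """Sensitivity and precision >= 0.95 against generator ground truth
        at SNR 3 (quick 10-seed version of the full recovery contract)."""
        for seed in range(10):
            cfg = EphysSimConfig(
                peak_rate=80, tonic_rate=25, spike_amplitude=1.0,
                noise_sd=1 / 3, seed=seed,
            )
            sim = generate_grn_trace(cfg)
            rec_events, _ = remove_artifacts(
                window_spikes(
                    detect_spikes(normalize_baseline(bandpass_filter(sim.trace)))
                ),
                cfg.sample_rate,
            )
            truth = sim.spike_times[(sim.spike_times >= 0.1) & (sim.spike_times < 2.1)]
            det = np.array([e.time for e in rec_events])
            tol = 0.3e-3
            sens = np.mean([np.any(np.abs(det - t) <= tol) for t in truth])
            prec = np.mean([np.any(np.abs(truth - d) <= tol) for d in det])
            assert sens >= 0.95 and prec >= 0.95

    def test_unresponsive_sensillum_flagged(self):
        recs = []
        for stim, rate in [("sucrose", 30), ("NaCl", 20), ("quinine", 0), ("caffeine", 10)]:
            recs.append(
                FiringRecord("b1", "s1", "mid", stim, rate, np.zeros(20, dtype=int))
            )
            recs.append(
                FiringRecord("b1", "s2", "tip", stim, max(rate, 5), np.zeros(20, dtype=int))
            )
        flags = flag_unresponsive_sensilla(recs)
        assert not flags.set_index("sensillum_id").loc["s1", "responsive"]
        assert flags.set_index("sensillum_id").loc["s2", "responsive"]
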