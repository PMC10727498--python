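"""Filtering, spike detection, burst segmentation, galeal classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from sensilla import detect, simulate
from sensilla.core import SpikeTrain, VoltageTrace
from sensilla.simulate import SimulationConfig, StimulusEffect


def _trace(samples, location="Gal", fs=30000.0):
    return VoltageTrace(samples=np.asarray(samples, float), sample_rate=fs,
                        location=location)


def _filtfilt_gain(freq, low=300.0, high=2500.0, fs=30000.0, order=2):
    """Oracle: squared Butterworth magnitude at freq (forward-backward)."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    w, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = detect.bandpass_filter(_trace(np.zeros(60000)))
        assert np.all(out.samples == 0)

    @pytest.mark.parametrize("freq,lo,hi", [(1000.0, 0.9, 1.0), (50.0, 0.0, 0.05)])
    def test_sinusoid_attenuation_matches_transfer_oracle(self, freq, lo, hi):
        fs = 30000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = detect.bandpass_filter(_trace(x)).samples
        core = slice(int(0.5 * fs), int(1.5 * fs))  # avoid edge transients
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert lo <= ratio <= hi
        assert ratio == pytest.approx(_filtfilt_gain(freq), abs=0.02)

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ValueError):
            detect.bandpass_filter(_trace(np.zeros(60000)), low=0.0)
        with pytest.raises(ValueError):
            detect.bandpass_filter(_trace(np.zeros(60000)), low=300, high=20000)


class TestNormalize:
    def test_scale_invariance(self, rng):
        x = rng.normal(size=40000)
        a = detect.normalize_trace(_trace(x)).samples
        b = detect.normalize_trace(_trace(10.0 * x)).samples
        np.testing.assert_allclose(a, b)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            detect.normalize_trace(_trace(np.ones(40000)))

    def test_percentile_maps_to_one(self, rng):
        x = rng.normal(size=100000)
        out = detect.normalize_trace(_trace(x)).samples
        assert np.percentile(np.abs(out), 99.9) == pytest.approx(1.0)

    def test_threshold_commutes_with_normalization(self, rng):
        """Detection after normalisation = detection before with a scaled
        threshold."""
        cfg = SimulationConfig(seed=3, duration=1.2, n_bees=1)
        rec = simulate.simulate_dataset(cfg)[0]
        filt = detect.bandpass_filter(rec.trace)
        norm = detect.normalize_trace(filt)
        scale = np.percentile(np.abs(filt.samples), 99.9)
        t_norm = detect.detect_spikes(norm, threshold=0.5)
        t_raw = detect.detect_spikes(filt, threshold=0.5 * scale)
        np.testing.assert_array_equal(t_norm.times, t_raw.times)


class TestDetectSpikes:
    def test_flat_trace_empty_train(self):
        train = detect.detect_spikes(_trace(np.zeros(40000)), threshold=0.5)
        assert len(train) == 0

    def test_noiseless_templates_detected_exactly(self):
        cfg = SimulationConfig(seed=0, noise_sd=0.0, duration=1.2, n_bees=1)
        times = np.linspace(0.1, 1.0, 10)
        trains = pd.DataFrame({"time_s": times, "unit": ["LP1"] * 10})
        rec = simulate.render_trace(trains, cfg, "LPIII", np.random.default_rng(0))
        train = detect.detect_spikes(rec.trace, threshold=0.5 * 5.0)
        assert len(train) == 10
        idx_true = np.round(times * cfg.sample_rate)
        idx_det = np.round(train.times * cfg.sample_rate)
        assert np.all(np.abs(idx_det - idx_true) <= 1)

    def test_recall_precision_at_snr5(self):
        """>= 95% recall and precision at SNR 5 with default threshold."""
        recalls, precisions = [], []
        for s in range(100):
            cfg = SimulationConfig(seed=s, duration=1.2, n_bees=1, noise_sd=0.2)
            r = np.random.default_rng(s)
            times = np.sort(r.uniform(0.05, 1.15, size=100))
            times = times[np.diff(np.concatenate([[0], times])) > 0.003]
            trains = pd.DataFrame({"time_s": times, "unit": ["LP1"] * len(times)})
            rec = simulate.render_trace(trains, cfg, "LPIII", r)
            norm = detect.normalize_trace(detect.bandpass_filter(rec.trace))
            train = detect.detect_spikes(norm)
            if len(train) == 0:
                recalls.append(0.0)
                precisions.append(0.0)
                continue
            d = np.abs(train.times[:, None] - times[None, :])
            precisions.append(np.mean(d.min(axis=1) < 0.001))
            recalls.append(np.mean(d.min(axis=0) < 0.001))
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_time_reversal_gives_reversed_spikes(self):
        """Zero-phase contract: reversing the trace reverses spike times."""
        cfg = SimulationConfig(seed=5, duration=1.2, n_bees=1)
        rec = simulate.simulate_dataset(cfg)[3]  # an LP trace
        fwd = detect.normalize_trace(detect.bandpass_filter(rec.trace))
        rev = fwd.with_samples(fwd.samples[::-1].copy())
        t_fwd = detect.detect_spikes(fwd, threshold=0.5)
        t_rev = detect.detect_spikes(rev, threshold=0.5)
        n = fwd.samples.size
        expected = np.sort((n - 1) / fwd.sample_rate - t_fwd.times)
        np.testing.assert_allclose(np.sort(t_rev.times), expected, atol=1e-9)


class TestBursts:
    def test_single_spike_is_its_own_eob(self):
        train = SpikeTrain(times=[0.5], peak_amplitudes=[1.0])
        bs = detect.detect_bursts(train)
        assert len(bs) == 1
        assert bs.bursts[0][1] == 0

    def test_constructed_isi_partition(self):
        # ISIs 10, 10, 80, 10, 10 ms with 40 ms threshold -> 3 + 3 spikes
        times = np.cumsum([0.1, 0.01, 0.01, 0.08, 0.01, 0.01])
        train = SpikeTrain(times=times, peak_amplitudes=np.ones(6))
        bs = detect.detect_bursts(train, isi_threshold=0.04)
        assert len(bs) == 2
        members = [m.tolist() for m, _ in bs.bursts]
        assert members == [[0, 1, 2], [3, 4, 5]]
        assert [e for _, e in bs.bursts] == [2, 5]

    def test_empty_train(self):
        bs = detect.detect_bursts(SpikeTrain(times=[], peak_amplitudes=[]))
        assert len(bs) == 0

    def test_partition_is_total_and_order_preserving(self, rng):
        for _ in range(20):
            times = np.sort(rng.uniform(0, 5, size=rng.integers(1, 80)))
            times = times[np.diff(np.concatenate([[-1], times])) > 1e-4]
            train = SpikeTrain(times=times, peak_amplitudes=np.ones(times.size))
            bs = detect.detect_bursts(train, isi_threshold=0.06)
            concat = np.concatenate([m for m, _ in bs.bursts])
            np.testing.assert_array_equal(concat, np.arange(times.size))

    def test_burst_recovery_on_simulated_trains(self, archetypes, control_effect):
        """Recovered burst count within +-1 of truth in >=95% of noiseless
        trials."""
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            train = simulate.simulate_spike_train(
                archetypes["Gal1"], control_effect, 1.1, r
            )
            true_bursts = int((train["unit"] == "Gal2").sum())
            st = SpikeTrain(
                times=train["time_s"].to_numpy(),
                peak_amplitudes=np.ones(len(train)),
            )
            got = len(detect.detect_bursts(st))
            hits += abs(got - true_bursts) <= 1
        assert hits >= 95


class TestClassifyGaleal:
    def test_k_bursts_give_k_gal2_labels(self, archetypes, control_effect, rng):
        train_df = simulate.simulate_spike_train(
            archetypes["Gal1"], control_effect, 2.0, rng
        )
        st = SpikeTrain(
            times=train_df["time_s"].to_numpy(),
            peak_amplitudes=np.ones(len(train_df)),
        )
        labels, bursts = detect.classify_galeal(st)
        assert (labels.labels == "Gal2").sum() == len(bursts)

    def test_gal3_recovered_when_active(self):
        """>= 90% of true Gal3 spikes labelled Gal3 on OSR-like traces."""
        agree = []
        for s in range(10):
            cfg = SimulationConfig(seed=s, duration=1.2, n_bees=1,
                                   sensilla_per_location=1)
            rec = simulate.simulate_dataset(cfg)[0]  # Gal, OSR
            norm = detect.normalize_trace(detect.bandpass_filter(rec.trace))
            train = detect.detect_spikes(norm)
            labels, _ = detect.classify_galeal(train)
            truth = rec.truth
            t3 = truth.loc[truth["unit"] == "Gal3", "time_s"].to_numpy()
            if t3.size == 0:
                continue
            det3 = train.times[labels.labels == "Gal3"]
            if det3.size == 0:
                agree.append(0.0)
                continue
            d = np.abs(t3[:, None] - det3[None, :]).min(axis=1)
            agree.append(np.mean(d < 0.001))
        assert np.mean(agree) >= 0.9

    def test_no_gal3_when_silent(self):
        """Sucrose-like traces (Gal3 off) yield no Gal3 unit in >=95%."""
        clean = 0
        runs = 40
        for s in range(runs):
            cfg = SimulationConfig(seed=1000 + s, duration=1.2, n_bees=1,
                                   sensilla_per_location=1)
            recs = simulate.simulate_dataset(cfg)
            rec = next(
                r for r in recs
                if r.trace.location == "Gal" and r.trace.stimulus == "SUC"
            )
            norm = detect.normalize_trace(detect.bandpass_filter(rec.trace))
            train = detect.detect_spikes(norm)
            labels, _ = detect.classify_galeal(train)
            clean += (labels.labels == "Gal3").sum() == 0
        assert clean / runs >= 0.95

    def test_noiseless_count_matches_resolvable_truth_exactly(self):
        """Noiseless detection recovers every resolvable ground-truth spike.

        Spikes from different units closer than the refractory separation
        superimpose into a single peak (overlap decomposition is out of
        scope), so the exact-count contract applies to the merged truth.
        """
        cfg = SimulationConfig(seed=9, duration=1.2, n_bees=1, noise_sd=0.0,
                               sensilla_per_location=1)
        rec = simulate.simulate_dataset(cfg)[0]
        filt = detect.bandpass_filter(rec.trace)
        train = detect.detect_spikes(filt, threshold=0.3)
        truth = np.sort(rec.truth["time_s"].to_numpy())
        n_coincident = int(np.sum(np.diff(truth) < detect.DEFAULT_REFRACTORY_S))
        assert n_coincident < len(truth) // 10  # overlaps are the exception
        assert len(truth) - n_coincident <= len(train) <= len(truth)
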