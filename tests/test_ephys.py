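"""Tests for the synthetic electrophysiology derivations."""

import numpy as np
import pytest

from twentyq import ephys


class TestSimulateUnits:
    def test_zero_rate_no_spikes(self):
        assert ephys.simulate_units(np.zeros((3, 10))).sum() == 0

    def test_unit_rate_one_spike_per_bin(self):
        spikes = ephys.simulate_units(np.ones((2, 10)))
        assert np.all(spikes == 1)

    def test_binomial_mean(self):
        spikes = ephys.simulate_units(np.full(10_000, 0.5), seed=0)
        se = 0.5 / np.sqrt(10_000)
        assert abs(spikes.mean() - 0.5) < 3 * se

    def test_seed_determinism(self):
        r = np.random.default_rng(3).uniform(size=(4, 50))
        assert np.array_equal(
            ephys.simulate_units(r, seed=7), ephys.simulate_units(r, seed=7)
        )

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ephys.simulate_units(np.array([1.5]))


class TestLfp:
    def test_constant_input_suppressed(self):
        y, pooled = ephys.lfp(np.full((2, 200), 0.7), trim=10)
        assert np.max(np.abs(y)) < 1e-6

    def test_band_gains(self):
        fs = ephys.FS_HZ
        t = np.arange(1000) / fs
        in_band = np.sin(2 * np.pi * 10 * t)
        out_band = np.sin(2 * np.pi * 1 * t)
        y_in, _ = ephys.lfp(in_band)
        y_out, _ = ephys.lfp(out_band)
        mid = slice(200, 800)
        gain_in = np.abs(y_in[0][mid]).max()
        gain_out = np.abs(y_out[0][mid]).max()
        assert 0.7 <= gain_in <= 1.0
        assert gain_out < 0.1

    def test_linearity(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        ya, _ = ephys.lfp(a)
        yb, _ = ephys.lfp(b)
        yab, _ = ephys.lfp(a + b)
        assert np.allclose(yab, ya + yb, atol=1e-10)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ephys.lfp(np.zeros(4))


class TestTimeFrequency:
    def test_zero_signal_zero_power(self):
        spec = ephys.time_frequency(np.zeros(100))
        assert np.allclose(spec.power, 0.0)
        assert spec.freqs_hz[0] == 4.0 and spec.freqs_hz[-1] == 32.0

    def test_burst_localised_in_time_and_frequency(self):
        fs = ephys.FS_HZ
        t = np.arange(256) / fs
        x = np.zeros_like(t)
        burst = slice(100, 156)
        x[burst] = np.sin(2 * np.pi * 8 * t[burst])
        spec = ephys.time_frequency(x)
        row8 = np.where(spec.freqs_hz == 8.0)[0][0]
        inside = spec.power[:, 110:146]
        peak_row = np.argmax(inside.mean(axis=1))
        assert abs(int(peak_row) - int(row8)) <= 1
        assert inside[row8].mean() > 5 * spec.power[row8, :50].mean() + 1e-12

    def test_energy_scales_with_amplitude(self, rng):
        x = rng.normal(size=200)
        e1 = ephys.time_frequency(x).power.sum()
        e2 = ephys.time_frequency(2 * x).power.sum()
        e3 = ephys.time_frequency(3 * x).power.sum()
        assert e1 < e2 < e3


class TestCfc:
    def test_identical_rows_all_ones(self):
        spec = ephys.Spectrogram(
            times_ms=np.arange(50) * 16.0,
            freqs_hz=np.arange(4, 7),
            power=np.tile(np.abs(np.sin(np.arange(50) / 3)) + 0.1, (3, 1)),
        )
        assert np.allclose(ephys.cfc_matrix(spec), 1.0, atol=1e-12)

    def test_independent_noise_near_zero(self, rng):
        power = np.abs(rng.normal(size=(5, 4000)))
        spec = ephys.Spectrogram(
            times_ms=np.arange(4000) * 16.0, freqs_hz=np.arange(4, 9), power=power
        )
        c = ephys.cfc_matrix(spec)
        off = c[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_constant_rows_report_zero(self):
        power = np.vstack([np.ones(30), np.abs(np.sin(np.arange(30)))])
        spec = ephys.Spectrogram(
            times_ms=np.arange(30) * 16.0, freqs_hz=np.arange(4, 6), power=power
        )
        c = ephys.cfc_matrix(spec)
        assert c[0, 1] == 0.0
        assert c[0, 0] == 1.0

    def test_too_short_rejected(self):
        spec = ephys.Spectrogram(
            times_ms=np.zeros(1), freqs_hz=np.arange(4, 6), power=np.ones((2, 1))
        )
        with pytest.raises(ValueError):
            ephys.cfc_matrix(spec)


class TestErpCompare:
    def test_identical_traces_zero_difference(self, rng):
        x = rng.normal(size=(3, 120))
        cmp = ephys.erp_compare(x, x, onset_bin=60)
        assert np.allclose(cmp.difference, 0.0, atol=1e-12)
        assert cmp.latency_standard_ms == cmp.latency_violation_ms

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ephys.erp_compare(rng.normal(size=(2, 50)), rng.normal(size=(2, 60)), 10)


class TestDopamineTrace:
    def test_constant_gamma_no_peaks(self):
        g = np.ones(96)
        labels = [(0, r) for r in ["prompt"] * 32 + ["question"] * 32 + ["answer"] * 32]
        dt = ephys.dopamine_trace(g, labels)
        assert dt.peak_heights == []

    def test_peaks_fall_in_answer_epochs(self, solo_result):
        """Phasic precision peaks coincide with the times answers are given
        (within one bin) during the questioning exchanges."""
        ag = solo_result.agents["agent"]
        g, labels = ag.dopamine_series()
        dt = ephys.dopamine_trace(g, labels)
        peaks = dict(zip(dt.peak_exchanges, dt.peak_bins))
        for k in range(4):
            role = labels[peaks[k]][1]
            # allow +-1 bin around the answer epoch boundary
            neighbours = {labels[max(peaks[k] - 1, 0)][1], labels[min(peaks[k] + 1, len(labels) - 1)][1]}
            assert role == "answer" or "answer" in neighbours

    def test_gamma_positive_throughout(self, solo_result):
        g, _ = solo_result.agents["agent"].dopamine_series()
        assert np.all(g > 0)


class TestNestedOscillations:
    def test_gamma_envelope_locked_to_word_onsets(self, solo_result):
        """High-frequency envelope energy at the lexical level concentrates
        within 64 ms of word onsets (transients recurring at ~4 Hz)."""
        ag = solo_result.agents["agent"]
        L, _ = ag.lower_session(exchanges=[1])
        labels = ag.log[0]["lower"][0].unit_labels
        keep = [j for j, (t, fn, st) in enumerate(labels) if fn == "syntax"]
        X = L[:, keep].T
        filtered, _ = ephys.lfp(X)
        env = np.zeros(X.shape[1])
        active = 0
        for row in filtered:
            if np.abs(row).max() < 1e-9:
                continue
            spec = ephys.time_frequency(row)
            env += spec.power[spec.band_rows(16, 31)].mean(axis=0)
            active += 1
        env /= max(active, 1)
        near = np.zeros(X.shape[1], bool)
        for onset in range(0, X.shape[1], 16):
            near[onset:onset + 4] = True
        assert env[near].mean() > env[~near].mean()

    def test_lower_level_transients_sharper(self, solo_result):
        """Lexical-level transients reach half peak faster than conceptual
        ones in matched epochs (nesting of timescales)."""
        ag = solo_result.agents["agent"]

        def half_rise(sig):
            d = np.abs(sig - sig[0])
            pk = d.max()
            if pk < 1e-3:
                return None
            return int(np.argmax(d >= pk / 2))

        lower_rises, upper_rises = [], []
        for entry in ag.log:
            if entry["exchange"] > 3:
                continue
            for tr in entry["lower"]:
                for j in range(tr.s.shape[1]):
                    r = half_rise(tr.s[:, j])
                    if r is not None:
                        lower_rises.append(r)
            up = entry["upper"]
            for j in range(up.s.shape[1]):
                r = half_rise(up.s[:, j])
                if r is not None:
                    upper_rises.append(r)
        assert np.median(lower_rises) < np.median(upper_rises)
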