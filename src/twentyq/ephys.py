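"""Synthetic neurophysiology derived from belief-updating traces.

State expectations recorded every 16 ms bin (sampling rate 62.5 Hz) stand in
for population firing rates; their log transforms for depolarisations.  From
these the module derives the standard readouts: spike rasters (binomial
sampling per bin), simulated local field potentials (zero-phase band-pass of
pooled expectations, 4-32 Hz), time-frequency decompositions (complex Morlet
wavelet amplitude), amplitude-amplitude cross-frequency coupling matrices,
violation (mismatch) waveform comparisons, and the expected-precision trace
read as a phasic dopamine signal.

All filtering operators are linear and deterministic; raster sampling is the
only stochastic element and is fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "FS_HZ",
    "Spectrogram",
    "simulate_units",
    "lfp",
    "time_frequency",
    "cfc_matrix",
    "erp_compare",
    "ErpComparison",
    "dopamine_trace",
    "DopamineTrace",
]

#: sampling rate implied by 16 ms bins
FS_HZ = 1000.0 / 16.0


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def simulate_units(
    rates: np.ndarray, seed: int | np.random.Generator = 0, n_trials: int = 1
) -> np.ndarray:
    """Spike rasters: one binomial draw per unit per 16 ms bin.

    ``rates`` holds expected rates in [0, 1] (shape ``[units, bins]`` or
    ``[bins]``); the success probability of each draw is the expected rate.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("expected rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(n_trials, rates)


# ---------------------------------------------------------------------------
# LFP / band-pass filtering
# ---------------------------------------------------------------------------


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 2):
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    return sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def lfp(
    x: np.ndarray,
    band: tuple[float, float] = (4.0, 32.0),
    fs: float = FS_HZ,
    order: int = 2,
    trim: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase band-pass of per-unit time series; returns (per-unit, pooled).

    ``x`` has shape ``[units, bins]`` or ``[bins]``.  The filter is a
    two-pass (forward-backward) IIR band-pass of the given order per pass,
    so it is linear, deterministic and phase-free; DC is removed by the
    band.  ``trim`` drops that many warm-up bins from each edge.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sos = _bandpass_sos(band, fs, order)
    if x.shape[1] <= 2 * sos.shape[0] + 1:
        raise ValueError("signal shorter than the filter warm-up length")
    padlen = min(x.shape[1] - 1, 24)
    y = sps.sosfiltfilt(sos, x, axis=1, padlen=padlen)
    if trim:
        y = y[:, trim:-trim]
    pooled = y.sum(axis=0)
    return y, pooled


# ---------------------------------------------------------------------------
# time-frequency analysis
# ---------------------------------------------------------------------------


@dataclass
class Spectrogram:
    """Amplitude envelope per frequency (4-32 Hz by default) and time bin."""

    times_ms: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # [n_freqs, n_bins], nonnegative amplitude

    def band_rows(self, lo: float, hi: float) -> np.ndarray:
        return np.where((self.freqs_hz >= lo) & (self.freqs_hz <= hi))[0]


def time_frequency(
    x: np.ndarray,
    fs: float = FS_HZ,
    freqs: np.ndarray | None = None,
    wavelet_width: float = 7.0,
    bin_ms: float = 16.0,
) -> Spectrogram:
    """Complex Morlet wavelet amplitude per frequency, time-aligned to bins.

    Uses a continuous wavelet transform with a Morlet of the given width
    (cycles parameter); frequencies default to 4-32 Hz in 1 Hz steps.
    """
    x = np.asarray(x, dtype=float).ravel()
    if freqs is None:
        freqs = np.arange(4.0, 33.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    # complex Morlet: centre frequency C = width / (2 pi) with unit-variance
    # Gaussian envelope (bandwidth B = 2) reproduces the standard width-w
    # Morlet; scale s maps to frequency f = C * fs / s.
    C = wavelet_width / (2.0 * np.pi)
    wavelet = pywt.ContinuousWavelet(f"cmor2.0-{C:.6f}")
    scales = C * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    power = np.abs(coeffs)
    times = np.arange(x.size) * bin_ms
    return Spectrogram(times_ms=times, freqs_hz=freqs, power=power)


def cfc_matrix(spec: Spectrogram) -> np.ndarray:
    """Amplitude-amplitude coupling: correlations between frequency rows.

    Pearson correlation between the amplitude time-courses of every pair of
    frequencies; symmetric with unit diagonal.  Constant rows carry no
    amplitude fluctuations and their correlations are reported as 0.
    """
    p = np.asarray(spec.power, dtype=float)
    if p.shape[1] < 2:
        raise ValueError("cross-frequency coupling needs at least 2 time bins")
    std = p.std(axis=1)
    ok = std > 0
    z = np.zeros_like(p)
    z[ok] = (p[ok] - p[ok].mean(axis=1, keepdims=True)) / std[ok, None]
    corr = (z @ z.T) / p.shape[1]
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# violation (mismatch) comparison
# ---------------------------------------------------------------------------


@dataclass
class ErpComparison:
    """Filtered responses of two matched runs and their difference waveform."""

    filtered_standard: np.ndarray
    filtered_violation: np.ndarray
    pooled_standard: np.ndarray
    pooled_violation: np.ndarray
    difference: np.ndarray
    latency_standard_ms: float
    latency_violation_ms: float
    onset_bin: int


def erp_compare(
    trace_standard: np.ndarray,
    trace_violation: np.ndarray,
    onset_bin: int,
    band: tuple[float, float] = (4.0, 32.0),
    fs: float = FS_HZ,
    bin_ms: float = 16.0,
    window: int | None = None,
) -> ErpComparison:
    """Compare matched runs differing only in the final (deviant) outcome.

    Both traces are band-passed per unit; the latency statistic is the time
    from ``onset_bin`` (the deviant outcome's onset) to the peak absolute
    pooled filtered response, within ``window`` bins of the onset if given.
    """
    a = np.atleast_2d(np.asarray(trace_standard, float))
    b = np.atleast_2d(np.asarray(trace_violation, float))
    if a.shape != b.shape:
        raise ValueError("matched runs must have identical trace shapes")
    fa, pa = lfp(a, band=band, fs=fs)
    fb, pb = lfp(b, band=band, fs=fs)
    stop = a.shape[1] if window is None else min(a.shape[1], onset_bin + window)
    seg_a = np.abs(pa[onset_bin:stop])
    seg_b = np.abs(pb[onset_bin:stop])
    lat_a = float(np.argmax(seg_a)) * bin_ms
    lat_b = float(np.argmax(seg_b)) * bin_ms
    return ErpComparison(
        filtered_standard=fa,
        filtered_violation=fb,
        pooled_standard=pa,
        pooled_violation=pb,
        difference=fb - fa,
        latency_standard_ms=lat_a,
        latency_violation_ms=lat_b,
        onset_bin=onset_bin,
    )


# ---------------------------------------------------------------------------
# dopamine
# ---------------------------------------------------------------------------


@dataclass
class DopamineTrace:
    """Concatenated precision iterates with epoch annotations and peaks."""

    gamma: np.ndarray
    labels: list[tuple[int, str]]  # (exchange, phrase role) per bin
    peak_bins: list[int]
    peak_heights: list[float]
    peak_exchanges: list[int]

    def answer_peaks(self) -> dict[int, float]:
        """Per-exchange peak height of gamma within the answer epoch."""
        out: dict[int, float] = {}
        for k in sorted({x for x, _ in self.labels}):
            idx = [
                i for i, (x, role) in enumerate(self.labels)
                if x == k and role == "answer"
            ]
            if idx:
                out[k] = float(np.max(self.gamma[idx]))
        return out


def dopamine_trace(
    gamma: np.ndarray, labels: list[tuple[int, str]], baseline: float = 1.0
) -> DopamineTrace:
    """Assemble the simulated dopamine signal and detect per-exchange peaks.

    The peak of each exchange is the bin with maximal gamma within that
    exchange; for a flat trace (constant precision) no peaks are reported.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] != len(labels):
        raise ValueError("one label per gamma bin is required")
    peak_bins, peak_heights, peak_exchanges = [], [], []
    for k in sorted({x for x, _ in labels}):
        idx = np.array([i for i, (x, _) in enumerate(labels) if x == k])
        seg = gamma[idx]
        if seg.max() - seg.min() < 1e-12 and abs(seg.max() - baseline) < 1e-9:
            continue  # flat: no phasic response
        j = int(np.argmax(seg))
        peak_bins.append(int(idx[j]))
        peak_heights.append(float(seg[j]))
        peak_exchanges.append(int(k))
    return DopamineTrace(
        gamma=gamma,
        labels=list(labels),
        peak_bins=peak_bins,
        peak_heights=peak_heights,
        peak_exchanges=peak_exchanges,
    )
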