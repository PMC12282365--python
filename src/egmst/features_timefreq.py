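"""Time-frequency (Smoothed Pseudo Wigner-Ville) and spectral features.

Each channel's EGM is mapped to a joint time-frequency energy distribution
from Cohen's class with separable time and lag (frequency) smoothing.  The
distribution is integrated over the QRS / post-QRS windows and over four
contiguous frequency bands per channel (40-Hz bands to 160 Hz for bipolar,
20-Hz bands to 80 Hz for unipolar), yielding per-window total energies and
fractional band energies — the eight-region tiling of 2 windows x 4 bands.
Spectral-domain features (central frequency and spectral peak count) come
from a Hann-tapered periodogram of the whole trace.

Kernel interpretation: the three distribution parameters (0.03, 0.15, 0.25)
are read as the time-smoothing window length and the lag window length, as
fractions of the analyzed signal length, and the Gaussian width of both
windows as a fraction of their length.  Acceptance of the distribution rests
on energy and marginal properties, not kernel-exact values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_model import Channel, EGMTrace

__all__ = [
    "TFSpec",
    "DEFAULT_TF_SPEC",
    "spwvd",
    "band_energies",
    "central_frequency",
    "spectral_peaks",
    "tf_features",
    "channel_bands",
]

BIPOLAR_BANDS: tuple[tuple[float, float], ...] = ((0, 40), (40, 80), (80, 120), (120, 160))
UNIPOLAR_BANDS: tuple[tuple[float, float], ...] = ((0, 20), (20, 40), (40, 60), (60, 80))

#: Spectral peaks must have at least this prominence relative to the PSD max.
PEAK_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class TFSpec:
    time_param: float = 0.03
    freq_param: float = 0.15
    kernel_shape: float = 0.25

    def bands(self, kind: Channel) -> tuple[tuple[float, float], ...]:
        return UNIPOLAR_BANDS if kind is Channel.UNIPOLAR else BIPOLAR_BANDS

    def band_max(self, kind: Channel) -> float:
        return self.bands(kind)[-1][1]


DEFAULT_TF_SPEC = TFSpec()


def _odd(n: int) -> int:
    n = max(3, int(round(n)))
    return n if n % 2 == 1 else n + 1


def spwvd(x: np.ndarray, fs: float, tf_spec: TFSpec = DEFAULT_TF_SPEC,
          t_step: int | None = None, n_freq: int | None = None
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed Pseudo Wigner-Ville distribution of a real signal.

    Parameters
    ----------
    x : real signal (length >= 64); the analytic signal is taken internally
        to suppress cross-terms between positive and negative frequencies.
    fs : sampling rate (Hz).
    t_step : stride between evaluated time columns (defaults to ~128 columns).
    n_freq : number of frequency bins over [0, fs/2].

    Returns
    -------
    (tfr, t_idx, freqs) where ``tfr`` is (len(t_idx), len(freqs)) in energy
    density units: sum(tfr) * dt * df equals the signal energy sum(x^2)/fs
    (normalization enforced).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError(f"signal too short for SPWVD: {n} < 64 samples")
    if t_step is None:
        t_step = max(1, n // 128)

    z = sps.hilbert(x)
    # time-smoothing window g (unit sum) and lag window h (h[0] = 1)
    lg = _odd(tf_spec.time_param * n)
    lh = _odd(tf_spec.freq_param * n)
    g = sps.windows.gaussian(lg, std=tf_spec.kernel_shape * lg)
    g = g / g.sum()
    m_max = (lh - 1) // 2
    h = sps.windows.gaussian(lh, std=tf_spec.kernel_shape * lh)
    h = h / h[m_max]

    if n_freq is None:
        n_freq = 1
        while n_freq < max(128, 2 * lh):
            n_freq *= 2

    t_idx = np.arange(0, n, t_step)
    zp = np.pad(z, (m_max, m_max))
    # instantaneous autocorrelation r[m, t] = z[t+m] z*[t-m], time-smoothed by g
    rows = []
    for m in range(m_max + 1):
        r = zp[m_max + m: m_max + m + n] * np.conj(zp[m_max - m: m_max - m + n])
        rows.append(r)
    r = np.asarray(rows)  # (m_max+1, n)
    r = sps.fftconvolve(r, g[None, :], mode="same", axes=1)[:, t_idx]

    # assemble kernel over lags -m_max..m_max into FFT buffer of length n_freq
    K = np.zeros((n_freq, t_idx.size), dtype=complex)
    K[0] = h[m_max] * r[0]
    for m in range(1, m_max + 1):
        K[m] = h[m_max + m] * r[m]
        K[n_freq - m] = h[m_max - m] * np.conj(r[m])
    W = np.fft.fft(K, axis=0).real  # (n_freq, n_times); bin m -> f = m*fs/(2*n_freq)

    keep = n_freq // 2 + 1
    W = W[:keep].T  # (n_times, keep)
    freqs = np.arange(keep) * fs / (2 * n_freq)
    dt = t_step / fs
    df = fs / (2 * n_freq)
    energy = float(np.sum(x ** 2)) / fs
    raw = float(W.sum()) * dt * df
    if raw > 0 and energy > 0:
        W = W * (energy / raw)
    return W, t_idx, freqs


def band_energies(tfr: np.ndarray, t_idx: np.ndarray, freqs: np.ndarray,
                  window: tuple[int, int], bands: tuple[tuple[float, float], ...],
                  fs: float, t_step: int) -> tuple[float, list[float]]:
    """Window energy over the full band range and fractional energy per band.

    Energies are non-negativity-clipped per band before normalization so the
    fractions are valid proportions despite the distribution's (small)
    negative side-lobes.  Returns (total, fractions); fractions are NaN when
    the window energy is zero.
    """
    a, b = window
    cols = (t_idx >= a) & (t_idx < b)
    if not np.any(cols):
        return 0.0, [float("nan")] * len(bands)
    dt = t_step / fs
    df = float(freqs[1] - freqs[0]) if freqs.size > 1 else 1.0
    sub = tfr[cols]
    f_max = bands[-1][1]
    vals = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi) if hi < f_max else (freqs >= lo) & (freqs <= hi)
        vals.append(max(0.0, float(sub[:, sel].sum()) * dt * df))
    total = float(sum(vals))
    if total <= 0:
        return 0.0, [float("nan")] * len(bands)
    return total, [v / total for v in vals]


def _psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    f, p = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
    return f, p


def central_frequency(x: np.ndarray, fs: float, band_max: float) -> float:
    """PSD-amplitude-weighted mean frequency (Hz) over [0, band_max]."""
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError("window too short for a spectral estimate (< 32 samples)")
    f, p = _psd(x, fs)
    sel = f <= band_max
    f, p = f[sel], p[sel]
    tot = float(p.sum())
    if tot <= 0:
        return float("nan")
    return float(np.sum(f * p) / tot)


def spectral_peaks(x: np.ndarray, fs: float, band_max: float) -> int:
    """Number of PSD local maxima with prominence >= 5% of the PSD maximum."""
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError("window too short for a spectral estimate (< 32 samples)")
    f, p = _psd(x, fs)
    sel = f <= band_max
    p = p[sel]
    mx = float(p.max(initial=0.0))
    if mx <= 0:
        return 0
    # pad so maxima at the band edges are countable
    padded = np.concatenate([[0.0], p, [0.0]])
    peaks, _ = sps.find_peaks(padded, prominence=PEAK_PROMINENCE_FRACTION * mx)
    return int(peaks.size)


def _decimation_factor(fs: float, band_max: float) -> int:
    """Largest decimation keeping a comfortable margin above the top band."""
    return max(1, int(fs // (3.2 * band_max)))


def _tf_channel_features(trace: EGMTrace, prefix: str, win_names: tuple[str, str],
                         tf_spec: TFSpec) -> dict[str, float]:
    """Registry time-frequency + spectral features for one channel."""
    from .preprocessing import segment  # local import to avoid cycle at import time

    bands = tf_spec.bands(trace.kind)
    f_max = tf_spec.band_max(trace.kind)
    q = _decimation_factor(trace.fs, f_max)
    q = max(1, min(q, trace.n_samples // 64))  # keep >= 64 samples for the kernel
    x = trace.samples
    if q > 1:
        x = sps.decimate(x, q, ftype="fir", zero_phase=True)
    fs_d = trace.fs / q
    t_step = max(1, x.size // 128)
    tfr, t_idx, freqs = spwvd(x, fs_d, tf_spec, t_step=t_step)

    wins = segment(trace)
    out: dict[str, float] = {}
    for wkey, wname in zip(("QRS", "post"), win_names):
        a, b = wins[wkey]
        total, fracs = band_energies(tfr, t_idx, freqs, (a // q, max(a // q + 1, b // q)),
                                     bands, fs_d, t_step)
        out[f"E_{prefix}_{wname}"] = total
        for (lo, hi), fr in zip(bands, fracs):
            out[f"R_{prefix}_{wname}_{int(lo)}_{int(hi)}"] = fr
    out[f"f_{prefix}"] = central_frequency(trace.samples, trace.fs, f_max)
    out[f"P_{prefix}"] = float(spectral_peaks(trace.samples, trace.fs, f_max))
    return out


def tf_features(uni: EGMTrace, bip: EGMTrace,
                tf_spec: TFSpec = DEFAULT_TF_SPEC) -> dict[str, float]:
    """All time-frequency and spectral registry features for one point."""
    out = _tf_channel_features(bip, "B", ("QRS", "P"), tf_spec)
    out.update(_tf_channel_features(uni, "U", ("QRS", "T"), tf_spec))
    return out


def channel_bands(kind: Channel) -> tuple[tuple[float, float], ...]:
    return UNIPOLAR_BANDS if kind is Channel.UNIPOLAR else BIPOLAR_BANDS
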